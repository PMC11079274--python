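"""Digital brain-tumor phantom and BOLD forward simulator.

The phantom is a labeled head volume with a unilateral lesion — a
contrast-enhancing shell around a necrotic core, surrounded by edema —
embedded in one hemisphere of a grey-matter / white-matter / CSF background,
plus a small artery region. Each compartment carries ground-truth relative
blood volume (rCBV, dimensionless a.u.), mean transit time (MTT, s) and
baseline signal S0, from which a ground-truth rCBF map follows by the
central volume theorem.

The forward simulator builds the arterial concentration as a scaled dOHb
trace, convolves it with each compartment's mono-exponential residue kernel
(exactly the discretization the inverse fit uses — see
:mod:`dohbperf.kinetics`), and writes the voxel signal as a relative drop
from S0 with optional additive Gaussian noise:

    S_v(t) = S0_v · (1 - rCBV_v · (Ca ⊛ h_MTT_v)(t) · TR) + ε.

Artery voxels carry the input itself, S = S0·(1 - Ca). Because the forward
and inverse models share one discretization, noiseless simulation followed
by fitting recovers the truth to numerical precision — the central
correctness property of the whole pipeline.

Default compartment parameters put tissue signal drops in the few-percent
range typical of hypoxia-contrast BOLD (arterial peak drop k_a = 0.15); the
global rCBV scale is arbitrary, only ratios between compartments matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from dohbperf.kinetics import tissue_model
from dohbperf.stimulus import GasTraces
from dohbperf import io as dio

__all__ = [
    "CompartmentParams",
    "PhantomSpec",
    "TruthMaps",
    "BoldSeries",
    "LABELS",
    "build_phantom",
    "simulate_bold",
    "write_fixture",
    "read_fixture",
]

# compartment label codes (0 = background/air)
LABELS = {
    "GM": 1,
    "WM": 2,
    "CSF": 3,
    "artery": 4,
    "CE": 5,
    "necrosis": 6,
    "edema": 7,
}
_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class CompartmentParams:
    """Ground-truth perfusion parameters of one tissue compartment."""

    rcbv: float  # relative blood volume, a.u. >= 0
    mtt: float  # mean transit time, s > 0
    s0: float  # baseline signal, a.u. > 0

    def __post_init__(self) -> None:
        if self.rcbv < 0:
            raise ValueError(f"rcbv must be >= 0, got {self.rcbv}")
        if self.mtt <= 0:
            raise ValueError(f"mtt must be > 0, got {self.mtt}")
        if self.s0 <= 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")


def _default_compartments() -> dict[str, CompartmentParams]:
    # rCBV ratios follow the cohort GM/WM/CE/edema means; MTTs are the
    # cohort means. Necrosis is hypoperfused with a long transit time; CSF
    # is nearly avascular. The artery's rcbv/mtt are placeholders — its
    # signal is the input curve itself.
    return {
        "GM": CompartmentParams(rcbv=0.29, mtt=3.5, s0=800.0),
        "WM": CompartmentParams(rcbv=0.24, mtt=3.9, s0=850.0),
        "CSF": CompartmentParams(rcbv=0.02, mtt=2.0, s0=500.0),
        "artery": CompartmentParams(rcbv=1.0, mtt=1.0, s0=600.0),
        "CE": CompartmentParams(rcbv=0.53, mtt=4.0, s0=750.0),
        "necrosis": CompartmentParams(rcbv=0.05, mtt=6.0, s0=700.0),
        "edema": CompartmentParams(rcbv=0.36, mtt=3.7, s0=780.0),
    }


@dataclass
class PhantomSpec:
    """Geometry, acquisition and compartment parameters of the phantom.

    Acquisition defaults mirror the protocol this pipeline targets:
    2.5 mm isotropic voxels, TR 1.8 s, TE 30 ms, 160 volumes. The default
    24×24×12 grid is a desk-scale head; all geometry scales with the grid.
    """

    nx: int = 24
    ny: int = 24
    nz: int = 12
    voxel_size: float = 2.5  # mm, isotropic
    n_volumes: int = 160
    tr: float = 1.8  # s
    te: float = 0.030  # s, metadata (used only by the log-domain conversion)
    compartments: dict[str, CompartmentParams] = field(
        default_factory=_default_compartments
    )
    noise_sd: float = 8.0  # additive Gaussian, signal units (GM tSNR ~ 100)
    aif_amplitude: float = 0.15  # k_a: peak arterial fractional signal drop
    lesion_center_frac: tuple[float, float, float] = (0.72, 0.5, 0.5)
    lesion_radii_frac: tuple[float, float, float] = (0.07, 0.12, 0.18)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 4:
            raise ValueError("grid dims must be >= 4 voxels")
        if self.tr <= 0 or self.voxel_size <= 0 or self.n_volumes < 1:
            raise ValueError("tr, voxel_size and n_volumes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        r_nec, r_ce, r_ed = self.lesion_radii_frac
        if not 0 < r_nec < r_ce < r_ed:
            raise ValueError("lesion radii must be nested: necrosis < CE < edema")


@dataclass
class TruthMaps:
    """Ground-truth label and perfusion volumes.

    rCBF = rCBV/MTT × 30 voxelwise wherever label != 0; MTT and rCBF are 0
    in the background.
    """

    labels: np.ndarray
    rcbv: np.ndarray
    mtt: np.ndarray
    rcbf: np.ndarray
    voxel_size: float

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels > 0

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


@dataclass
class BoldSeries:
    """4-D BOLD signal with acquisition metadata.

    ``baseline`` is the (start, stop) index range of the normoxic baseline
    used to estimate S0.
    """

    data: np.ndarray  # (x, y, z, t), arbitrary units
    tr: float
    te: float
    voxel_size: float
    baseline: tuple[int, int]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        b0, b1 = self.baseline
        if not 0 <= b0 < b1 <= self.data.shape[-1]:
            raise ValueError(f"baseline window {self.baseline} outside series")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def baseline_window(self) -> slice:
        return slice(*self.baseline)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def build_phantom(spec: PhantomSpec, seed: int | None = None) -> TruthMaps:
    """Build the labeled head volume and its ground-truth perfusion maps.

    Deterministic given the seed. The lesion (necrotic core, CE shell,
    edema halo) lies strictly in one hemisphere so that a mid-plane flipped
    mask lands in healthy tissue; a small artery region sits near the skull
    base on the contralateral side.
    """
    del seed  # geometry is fully deterministic; seed only matters for noise
    shape = (spec.nx, spec.ny, spec.nz)
    cx, cy, cz = (spec.nx - 1) / 2, (spec.ny - 1) / 2, (spec.nz - 1) / 2

    head = _ellipsoid(shape, (cx, cy, cz), (0.46 * spec.nx, 0.46 * spec.ny, 0.46 * spec.nz))
    wm = _ellipsoid(shape, (cx, cy, cz), (0.30 * spec.nx, 0.30 * spec.ny, 0.32 * spec.nz))
    csf = _ellipsoid(shape, (cx, cy, cz), (0.10 * spec.nx, 0.10 * spec.ny, 0.14 * spec.nz))

    labels = np.zeros(shape, dtype=np.uint8)
    labels[head] = LABELS["GM"]
    labels[wm] = LABELS["WM"]
    labels[csf] = LABELS["CSF"]

    # lesion: nested spheres in the right hemisphere (x > nx/2)
    lc = tuple(f * (n - 1) for f, n in zip(spec.lesion_center_frac, shape))
    radii = [f * spec.nx for f in spec.lesion_radii_frac]
    r_ed = radii[2]
    for axis, (c, n) in enumerate(zip(lc, shape)):
        if c - r_ed < 0 or c + r_ed > n - 1:
            raise ValueError(
                f"lesion (radius {r_ed:.1f} vox) does not fit the grid on axis {axis}"
            )
    if lc[0] - r_ed <= spec.nx / 2:
        raise ValueError("lesion crosses the midline; shrink it or move the center")
    edema = _ellipsoid(shape, lc, (r_ed,) * 3) & head
    ce = _ellipsoid(shape, lc, (radii[1],) * 3) & head
    nec = _ellipsoid(shape, lc, (radii[0],) * 3) & head
    labels[edema] = LABELS["edema"]
    labels[ce] = LABELS["CE"]
    labels[nec] = LABELS["necrosis"]

    # artery: a small block near the inferior midline, left hemisphere
    ax = slice(int(0.25 * spec.nx), int(0.25 * spec.nx) + 2)
    ay = slice(int(0.5 * spec.ny) - 1, int(0.5 * spec.ny) + 1)
    az = slice(1, 3)
    artery = np.zeros(shape, dtype=bool)
    artery[ax, ay, az] = True
    artery &= head
    if not artery.any():
        raise ValueError("artery block fell outside the head; enlarge the grid")
    labels[artery] = LABELS["artery"]

    rcbv = np.zeros(shape)
    mtt = np.zeros(shape)
    for name, code in LABELS.items():
        sel = labels == code
        if not sel.any():
            continue
        p = spec.compartments[name]
        rcbv[sel] = p.rcbv
        mtt[sel] = p.mtt
    rcbf = np.zeros(shape)
    tissue = labels > 0
    rcbf[tissue] = rcbv[tissue] / mtt[tissue] * 30.0
    return TruthMaps(labels=labels, rcbv=rcbv, mtt=mtt, rcbf=rcbf, voxel_size=spec.voxel_size)


def simulate_bold(
    truth: TruthMaps,
    gas: GasTraces,
    spec: PhantomSpec,
    seed: int | None = None,
) -> BoldSeries:
    """Forward-simulate the BOLD series from ground truth and gas traces.

    The arterial relative concentration is Ca(t) = k_a·dohb(t)/max(dohb)
    (zero throughout for a no-stimulus protocol). Tissue voxels follow the
    linear signal-domain model; artery voxels carry Ca itself. Additive
    Gaussian noise (sd ``spec.noise_sd``) is drawn independently per voxel
    and time point from a generator seeded with ``seed``.
    """
    n = spec.n_volumes
    if len(gas) < n:
        raise ValueError(
            f"gas trace has {len(gas)} samples but the scan needs {n}; "
            "build traces with n_samples=n_volumes"
        )
    dohb = np.asarray(gas.dohb[:n], dtype=float)
    peak = dohb.max()
    ca = spec.aif_amplitude * dohb / peak if peak > 0 else np.zeros(n)

    shape = truth.labels.shape
    s = np.zeros(shape + (n,))
    s0_map = np.zeros(shape)
    for name, code in LABELS.items():
        sel = truth.labels == code
        if not sel.any():
            continue
        s0_map[sel] = spec.compartments[name].s0

    artery = truth.compartment_mask("artery")
    tissue = (truth.labels > 0) & ~artery
    # group voxels by their (rcbv, mtt) pair: one convolution per pair
    pairs = np.stack([truth.rcbv[tissue], truth.mtt[tissue]], axis=1)
    for rcbv, mtt in np.unique(pairs, axis=0):
        sel = tissue & (truth.rcbv == rcbv) & (truth.mtt == mtt)
        c = rcbv * tissue_model(ca, mtt, spec.tr) if rcbv > 0 else np.zeros(n)
        if c.max() >= 1.0:
            name = _NAMES.get(int(truth.labels[sel][0]), "?")
            raise ValueError(
                f"compartment {name}: concentration reaches {c.max():.2f} >= 1 "
                "(signal would go non-positive); reduce rcbv or aif_amplitude"
            )
        s[sel] = s0_map[sel, None] * (1.0 - c)[None, :]
    s[artery] = s0_map[artery, None] * (1.0 - ca)[None, :]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        inside = truth.labels > 0
        s[inside] += rng.normal(0.0, spec.noise_sd, size=s[inside].shape)

    # baseline = samples acquired before the first dOHb excursion
    w = gas.baseline_window()
    stop = min(w.stop, n)
    return BoldSeries(
        data=s, tr=spec.tr, te=spec.te, voxel_size=spec.voxel_size,
        baseline=(0, max(stop, 1)),
    )


def write_fixture(truth: TruthMaps, bold: BoldSeries, directory) -> list[Path]:
    """Write phantom truth + BOLD series to a directory (NIfTI + JSON meta)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("labels", "rcbv", "mtt", "rcbf"):
        written.append(
            dio.save_volume(directory / f"truth_{name}.nii", getattr(truth, name), truth.voxel_size)
        )
    written.append(dio.save_volume(directory / "bold.nii", bold.data, bold.voxel_size))
    meta = {
        "tr": bold.tr,
        "te": bold.te,
        "voxel_size": bold.voxel_size,
        "baseline": list(bold.baseline),
    }
    meta_path = directory / "meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written.append(meta_path)
    return written


def read_fixture(directory) -> tuple[TruthMaps, BoldSeries]:
    """Read a phantom fixture written by :func:`write_fixture` (lossless)."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"fixture metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    vols = {}
    for name in ("labels", "rcbv", "mtt", "rcbf"):
        vols[name], vox = dio.load_volume(directory / f"truth_{name}.nii")
    bold_data, _ = dio.load_volume(directory / "bold.nii")
    truth = TruthMaps(
        labels=np.asarray(vols["labels"], dtype=np.uint8),
        rcbv=vols["rcbv"], mtt=vols["mtt"], rcbf=vols["rcbf"],
        voxel_size=meta["voxel_size"],
    )
    bold = BoldSeries(
        data=np.asarray(bold_data, dtype=float),
        tr=meta["tr"], te=meta["te"], voxel_size=meta["voxel_size"],
        baseline=tuple(meta["baseline"]),
    )
    return truth, bold
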