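"""Quality control: percent signal change, masked smoothing, stimulus R².

Before fitting perfusion, the analysis checks that the hypoxic stimulus
actually modulated the BOLD signal: the percent signal change trace in a
tissue mask should track the dOHb regressor, and the voxelwise coefficient
of determination of an ordinary least-squares fit against the regressor
summarizes data quality (a subject whose median R² is too low is excluded
rather than fitted).

The spatial smoother used throughout is an adaptive mean filter: an
unweighted cube-kernel mean restricted to in-mask voxels, with the divisor
equal to the count of valid neighbors, so voxels at the brain edge average
only over real tissue instead of bleeding in zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from dohbperf.phantom import BoldSeries

__all__ = [
    "QcMaps",
    "QcReport",
    "percent_bold_change",
    "adaptive_mean_filter",
    "regress_stimulus",
    "qc_gate",
]


@dataclass
class QcMaps:
    """Voxelwise stimulus-regression maps (NaN outside the mask)."""

    r2: np.ndarray  # coefficient of determination, in [0, 1]
    slope: np.ndarray  # signal units per regressor unit
    mask: np.ndarray


@dataclass
class QcReport:
    """Summary of in-mask R² used to gate a subject in or out."""

    passed: bool
    median_r2: float
    q1_r2: float
    q3_r2: float
    frac_above: float
    threshold: float
    n_voxels: int

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"QC {verdict}: median R2={self.median_r2:.3f} "
            f"(IQR {self.q1_r2:.3f}-{self.q3_r2:.3f}), "
            f"{100 * self.frac_above:.1f}% of {self.n_voxels} voxels above "
            f"threshold {self.threshold:.3f}"
        )


def percent_bold_change(
    bold: BoldSeries,
    mask: np.ndarray,
    baseline_window: slice | None = None,
) -> np.ndarray:
    """Mask-mean percent signal change per time point, relative to baseline.

    Spatial mean over the mask first, then 100·(S̄(t) − S̄_base)/S̄_base with
    S̄_base the temporal mean of that trace over the baseline window. The
    trace averages exactly to zero over the baseline window.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    w = baseline_window if baseline_window is not None else bold.baseline_window
    trace = bold.data[mask].mean(axis=0)
    base = trace[w].mean()
    if base == 0:
        raise ValueError("baseline mean is zero; cannot form percent change")
    return 100.0 * (trace - base) / base


def adaptive_mean_filter(
    bold: BoldSeries,
    mask: np.ndarray,
    width_mm: float = 7.0,
) -> BoldSeries:
    """Mask-restricted cube-kernel mean smoothing of the 4-D series.

    The kernel is a cube of side ceil(width_mm/voxel_size) voxels, rounded
    up to odd (3×3×3 for 7 mm at 2.5 mm voxels). Each in-mask voxel becomes
    the mean of the in-mask voxels inside its cube — the divisor adapts to
    the local count of valid neighbors, so edges are not diluted.
    Out-of-mask voxels pass through unchanged.
    """
    if width_mm <= 0:
        raise ValueError("width_mm must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    k = int(np.ceil(width_mm / bold.voxel_size))
    if k % 2 == 0:
        k += 1
    kernel = np.ones((k, k, k))
    maskf = mask.astype(float)
    counts = ndimage.convolve(maskf, kernel, mode="constant")
    out = bold.data.astype(float).copy()
    for t in range(bold.n_volumes):
        sums = ndimage.convolve(bold.data[..., t] * maskf, kernel, mode="constant")
        out[mask, t] = sums[mask] / counts[mask]
    return replace(bold, data=out)


def regress_stimulus(
    bold: BoldSeries,
    regressor: np.ndarray,
    mask: np.ndarray,
) -> QcMaps:
    """Voxelwise OLS of each time course on (intercept, regressor).

    Returns slope and R² per in-mask voxel. A voxel with zero temporal
    variance gets R² = 0. R² is invariant to affine rescaling of either
    the regressor or the signal.
    """
    regressor = np.asarray(regressor, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if len(regressor) != bold.n_volumes:
        raise ValueError("regressor length must equal the number of volumes")
    xc = regressor - regressor.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant regressor")
    y = bold.data[mask].astype(float)
    yc = y - y.mean(axis=1, keepdims=True)
    slope_v = (yc @ xc) / sxx
    syy = np.einsum("ij,ij->i", yc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_v = np.where(syy > 0, slope_v**2 * sxx / np.where(syy > 0, syy, 1.0), 0.0)
    r2_v = np.clip(r2_v, 0.0, 1.0)
    shape = mask.shape
    r2 = np.full(shape, np.nan)
    slope = np.full(shape, np.nan)
    r2[mask] = r2_v
    slope[mask] = slope_v
    return QcMaps(r2=r2, slope=slope, mask=mask)


def qc_gate(
    qc: QcMaps,
    mask: np.ndarray | None = None,
    r2_threshold: float = 0.1,
) -> QcReport:
    """Gate a subject on the median in-mask R².

    Fails when the median R² over the mask is below the threshold
    (default 0.1; the original analysis excluded one noisy subject without
    stating a cutoff, so the threshold is configurable).
    """
    mask = qc.mask if mask is None else (np.asarray(mask, dtype=bool) & qc.mask)
    vals = qc.r2[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite R2 values inside the mask")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return QcReport(
        passed=bool(med >= r2_threshold),
        median_r2=float(med),
        q1_r2=float(q1),
        q3_r2=float(q3),
        frac_above=float((vals >= r2_threshold).mean()),
        threshold=r2_threshold,
        n_voxels=int(vals.size),
    )
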