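"""End-tidal O2 stimulus protocol and the arterial dOHb regressor.

The respiratory protocol is a double hypoxic challenge delivered under
isocapnia: a normoxic baseline (P_ET_O2 95 mmHg), a step to hypoxia
(40 mmHg) for 60 s, a normoxic interlude, a second 60 s hypoxic step, and a
normoxic recovery. Each hypoxic plateau transiently raises arterial
deoxyhemoglobin, producing an endogenous susceptibility-contrast bolus.

End-tidal O2 is converted to arterial saturation with a Hill dissociation
curve (default p50 = 26.8 mmHg, cooperativity 2.7 — textbook adult values),
and the dOHb excess over baseline, clipped at zero, is the regressor used
for QC and as the shape of the arterial input in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusProtocol",
    "GasTraces",
    "build_protocol",
    "po2_to_sao2",
    "make_gas_traces",
]

_MAX_PO2 = 760.0  # mmHg, ambient pressure; end-tidal O2 cannot exceed it


@dataclass(frozen=True)
class StimulusProtocol:
    """A piecewise-constant programmed end-tidal O2 waveform.

    Parameters
    ----------
    segments
        Ordered ``(duration_s, peto2_mmhg)`` pairs.
    tr
        Sample spacing in seconds (the BOLD repetition time).
    petco2
        Constant end-tidal CO2 target in mmHg. Carried as metadata only:
        isocapnia is enforced by the gas blender, so no CO2 effect is
        modeled.
    """

    segments: tuple[tuple[float, float], ...]
    tr: float
    petco2: float = 40.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for duration, po2 in self.segments:
            if duration <= 0:
                raise ValueError(f"segment duration must be > 0, got {duration}")
            if not 0 < po2 < _MAX_PO2:
                raise ValueError(f"petO2 must be in (0, {_MAX_PO2}) mmHg, got {po2}")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")

    @property
    def total_duration(self) -> float:
        """Total protocol duration in seconds (sum of segment durations)."""
        return float(sum(d for d, _ in self.segments))

    def sample_times(self, n_samples: int | None = None) -> np.ndarray:
        """Sample grid t_k = k*tr.

        By default covers the protocol (all t_k < total duration); with
        ``n_samples`` the grid is exactly that long, extending past the
        protocol end if the scan outlasts the stimulus.
        """
        if n_samples is None:
            n_samples = int(np.ceil(self.total_duration / self.tr))
        return np.arange(n_samples) * self.tr

    def sample_peto2(self, n_samples: int | None = None) -> np.ndarray:
        """Piecewise-constant P_ET_O2 at t_k = k*tr.

        A sample takes the value of the segment containing t_k; a boundary
        sample belongs to the later segment. Samples past the protocol end
        hold the final segment's target.
        """
        t = self.sample_times(n_samples)
        starts = np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        targets = np.array([po2 for _, po2 in self.segments])
        return targets[idx]


@dataclass(frozen=True)
class GasTraces:
    """Sampled gas waveform and the derived arterial dOHb regressor.

    ``dohb`` is the arterial deoxyhemoglobin excess over baseline,
    ``saO2(t=0) - saO2(t)`` clipped at zero — dimensionless, zero during
    normoxia, positive during the hypoxic plateaus.
    """

    time: np.ndarray
    peto2: np.ndarray
    sao2: np.ndarray
    dohb: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.peto2) == len(self.sao2) == len(self.dohb) == n):
            raise ValueError("all traces must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    def baseline_window(self) -> slice:
        """Leading run of samples with zero dOHb (the normoxic baseline).

        For a no-stimulus protocol the window is the whole series.
        """
        nonzero = np.nonzero(self.dohb > 0)[0]
        stop = int(nonzero[0]) if nonzero.size else len(self.dohb)
        return slice(0, max(stop, 1))

    def to_table(self) -> "np.ndarray":
        """4-column array (time, petO2, saO2, dohb) for delimited export."""
        return np.column_stack([self.time, self.peto2, self.sao2, self.dohb])

    def save(self, path) -> None:
        np.savetxt(
            path,
            self.to_table(),
            header="time_s peto2_mmhg sao2 dohb",
            fmt="%.6f",
        )


def build_protocol(
    baseline_s: float = 60.0,
    hypoxia_s: float = 60.0,
    interlude_s: float = 30.0,
    recovery_s: float = 50.0,
    po2_normoxia: float = 95.0,
    po2_hypoxia: float = 40.0,
    tr: float = 1.8,
    petco2: float = 40.0,
) -> StimulusProtocol:
    """Build the five-segment double-hypoxia protocol.

    Pattern: baseline → hypoxia → normoxic interlude → hypoxia → recovery.
    Defaults give the 4 min 20 s (260 s) programmed waveform: 60 s at
    95 mmHg, 60 s at 40 mmHg, a 30 s interlude, a second 60 s hypoxic step,
    and 50 s of recovery (interlude and recovery are midpoints of the
    protocol's allowed 20–40 s and 40–60 s ranges).
    """
    if po2_hypoxia > po2_normoxia:
        raise ValueError(
            f"po2_hypoxia ({po2_hypoxia}) must not exceed po2_normoxia ({po2_normoxia})"
        )
    segments = (
        (baseline_s, po2_normoxia),
        (hypoxia_s, po2_hypoxia),
        (interlude_s, po2_normoxia),
        (hypoxia_s, po2_hypoxia),
        (recovery_s, po2_normoxia),
    )
    return StimulusProtocol(segments=segments, tr=tr, petco2=petco2)


def po2_to_sao2(po2, p50: float = 26.8, hill_n: float = 2.7):
    """Hill oxygen-dissociation curve: saO2 = po2^n / (po2^n + p50^n).

    Monotone increasing in po2, in [0, 1). Accepts scalars or arrays.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be >= 0")
    if p50 <= 0 or hill_n <= 0:
        raise ValueError("p50 and hill_n must be > 0")
    x = po2**hill_n
    out = x / (x + p50**hill_n)
    return float(out) if out.ndim == 0 else out


def make_gas_traces(
    protocol: StimulusProtocol,
    n_samples: int | None = None,
    p50: float = 26.8,
    hill_n: float = 2.7,
) -> GasTraces:
    """Sample the protocol and derive saturation and dOHb traces.

    ``n_samples`` extends (or truncates) the grid to match a scan that is
    longer than the stimulus; extra samples hold the final segment's target.
    """
    time = protocol.sample_times(n_samples)
    peto2 = protocol.sample_peto2(n_samples)
    sao2 = po2_to_sao2(peto2, p50=p50, hill_n=hill_n)
    dohb = np.clip(sao2[0] - sao2, 0.0, None)
    return GasTraces(time=time, peto2=peto2, sao2=sao2, dohb=dohb)
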