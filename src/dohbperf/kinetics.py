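"""Shared indicator-dilution discretization.

The forward simulator and the inverse fit must use the identical
discretization of the convolution model, otherwise discretization error
masquerades as parameter error. Both import from here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exp_residue_kernel", "tissue_model"]


def exp_residue_kernel(mtt: float, tr: float, n: int) -> np.ndarray:
    """Discretized mono-exponential residue kernel h(t) = exp(-t/MTT)/MTT.

    Sampled at t_k = k*tr and renormalized so that Σ h·tr = 1 over the n
    samples. Truncation error of the renormalization is negligible when the
    series length n·tr is much longer than MTT (≈288 s vs ≤8 s here).
    """
    if mtt <= 0:
        raise ValueError(f"mtt must be > 0, got {mtt}")
    t = np.arange(n) * tr
    h = np.exp(-t / mtt) / mtt
    return h / (h.sum() * tr)


def tissue_model(c_aif: np.ndarray, mtt: float, tr: float) -> np.ndarray:
    """Unit-rCBV tissue curve m(t) = (Ca ⊛ h_MTT)(t)·tr.

    Causal discrete convolution with left-Riemann weighting on the tr grid.
    """
    n = len(c_aif)
    h = exp_residue_kernel(mtt, tr, n)
    return np.convolve(c_aif, h)[:n] * tr
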