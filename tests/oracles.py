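"""Independent brute-force oracle for the deconvolution fit.

Exhaustive enumeration over an (rCBV, MTT) grid — no closed-form
projection, no optimizer — so it can stand as an independent check of
fit_voxel. The rCBV search is two-stage (coarse then fine around the coarse
argmin) purely to keep the enumeration affordable; both stages are plain
grid evaluations of the residual sum of squares.
"""

import numpy as np

from dohbperf.kinetics import tissue_model


def brute_force_fit(
    c_tissue,
    c_aif,
    tr,
    mtt_grid,
    rcbv_max=6.0,
    coarse_step=0.02,
    fine_step=2e-4,
):
    """Return the (rCBV, MTT) pair minimizing rss over the enumeration grid."""
    best = (np.inf, None, None)
    coarse = np.arange(0.0, rcbv_max + 1e-12, coarse_step)
    for mtt in mtt_grid:
        m = tissue_model(c_aif, mtt, tr)
        rss = np.sum((c_tissue[None, :] - coarse[:, None] * m[None, :]) ** 2, axis=1)
        i = int(np.argmin(rss))
        lo = max(coarse[i] - coarse_step, 0.0)
        fine = np.arange(lo, coarse[i] + coarse_step + 1e-12, fine_step)
        rss_f = np.sum((c_tissue[None, :] - fine[:, None] * m[None, :]) ** 2, axis=1)
        j = int(np.argmin(rss_f))
        if rss_f[j] < best[0]:
            best = (float(rss_f[j]), float(fine[j]), float(mtt))
    return best[1], best[2]
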