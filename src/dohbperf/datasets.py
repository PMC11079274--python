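"""Reference cohort measurements bundled for validating aggregation.

Per-patient ROI perfusion means (MTT in s, rCBV and rCBF in a.u.) and
demographics from the nine-patient brain-tumor cohort this pipeline models.
Eight subjects contribute perfusion rows (one was excluded for excessively
noisy BOLD); subject 7 has no identifiable contrast enhancement or edema,
so those entries are missing. These tables let :func:`cohort_summary` be
checked against independently published aggregate rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reference_cohort", "reference_ages"]

# columns per ROI: (MTT, rCBV, rCBF); None = compartment absent
_ROIS = ("GM", "WM", "CE", "flipped_CE", "edema", "flipped_edema")
_ROWS: dict[str, list[tuple[float, float, float] | None]] = {
    "1": [(2.7, 2.0, 45.6), (3.2, 1.8, 35.0), (3.6, 2.4, 67.3),
          (5.4, 1.0, 15.7), (5.9, 1.6, 24.0), (6.9, 1.3, 13.5)],
    "2": [(3.7, 4.4, 59.8), (3.9, 4.3, 59.2), (3.8, 5.2, 71.2),
          (3.8, 3.2, 55.1), (2.6, 4.0, 69.9), (3.6, 3.7, 74.0)],
    "4a": [(4.2, 5.2, 61.6), (4.9, 4.1, 46.8), (4.8, 7.8, 94.1),
           (6.5, 4.3, 42.2), (4.7, 4.6, 46.6), (5.4, 4.3, 42.5)],
    "5": [(3.8, 4.3, 55.5), (4.4, 3.0, 39.3), (5.0, 12.7, 122.6),
          (5.2, 6.4, 63.7), (4.8, 9.0, 93.3), (5.1, 10.5, 108.4)],
    "6": [(5.6, 1.7, 16.3), (6.2, 1.3, 14.1), (5.2, 4.9, 49.2),
          (5.9, 3.5, 29.8), (5.7, 1.7, 14.8), (5.9, 1.8, 17.3)],
    "7": [(3.1, 2.6, 46.2), (3.9, 2.0, 34.4), None, None, None, None],
    "8": [(1.9, 2.2, 95.2), (2.0, 2.0, 83.1), (1.6, 4.5, 210.2),
          (2.3, 1.6, 61.9), (1.4, 2.6, 132.9), (1.3, 1.4, 74.4)],
    "9": [(2.7, 1.1, 30.2), (2.9, 1.0, 29.2), (3.4, 1.4, 34.6),
          (3.8, 0.9, 23.3), (2.6, 1.1, 32.6), (2.9, 1.0, 32.1)],
}

_AGES = {"1": 77, "2": 58, "3": 59, "4a": 60, "5": 51, "6": 57, "7": 29, "8": 41, "9": 72}


def reference_cohort() -> pd.DataFrame:
    """Tidy per-subject ROI means: columns (subject, roi, metric, value)."""
    rows = []
    for subject, entries in _ROWS.items():
        for roi, entry in zip(_ROIS, entries):
            for metric, value in zip(
                ("mtt", "rcbv", "rcbf"),
                entry if entry is not None else (np.nan, np.nan, np.nan),
            ):
                rows.append(
                    {"subject": subject, "roi": roi, "metric": metric, "value": value}
                )
    return pd.DataFrame(rows)


def reference_ages() -> pd.Series:
    """Ages (years) of the nine enrolled subjects, indexed by subject id."""
    return pd.Series(_AGES, name="age")
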