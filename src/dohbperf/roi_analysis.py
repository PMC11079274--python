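"""ROI composition, contralateral flipped masks, and cohort statistics.

Tumor ROIs follow the radiological nesting: ``tumor`` is contrast
enhancement plus necrosis; ``whole_lesion`` additionally includes the
perilesional edema. Grey and white matter are analyzed after masking out
the whole lesion. Each lesion ROI also gets a contralateral counterpart by
mirroring it across the volume's left–right mid-plane, sampling homologous
healthy tissue.

Cohort aggregation reports mean, population standard deviation (divide by
n — the convention the reference cohort tables use), minimum and maximum
per ROI × metric, with rounding applied only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dohbperf.phantom import LABELS

__all__ = [
    "RoiSet",
    "flip_mask",
    "compose_rois",
    "roi_set_from_labels",
    "summarize_rois",
    "cohort_summary",
    "format_cohort_table",
    "compare_map_sets",
]

METRICS = ("mtt", "rcbv", "rcbf")


def flip_mask(mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mirror a mask about the grid mid-plane on the left–right axis.

    Index i maps to n-1-i; voxel count is preserved and the operation is an
    involution. Assumes the volume is approximately midline-centered.
    """
    return np.flip(np.asarray(mask), axis=axis).copy()


@dataclass
class RoiSet:
    """Named binary masks on one grid, including flipped counterparts."""

    masks: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)


def compose_rois(
    ce: np.ndarray,
    necrosis: np.ndarray,
    edema: np.ndarray,
    gm: np.ndarray,
    wm: np.ndarray,
    flip_axis: int = 0,
) -> RoiSet:
    """Compose the analysis ROIs from raw segmentation masks.

    Overlaps resolve by precedence necrosis > CE > edema (the nesting a
    radiologist would draw). ``tumor`` = CE ∪ necrosis; ``whole_lesion`` =
    tumor ∪ edema; GM and WM have the whole lesion removed. Flipped
    counterparts are attached for CE, edema, tumor and whole_lesion.
    """
    masks = [np.asarray(m, dtype=bool) for m in (ce, necrosis, edema, gm, wm)]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask grids differ: {sorted(shapes)}")
    ce, necrosis, edema, gm, wm = masks
    ce = ce & ~necrosis
    edema = edema & ~necrosis & ~ce
    tumor = ce | necrosis
    whole = tumor | edema
    out = {
        "GM": gm & ~whole,
        "WM": wm & ~whole,
        "CE": ce,
        "necrosis": necrosis,
        "edema": edema,
        "tumor": tumor,
        "whole_lesion": whole,
    }
    for name in ("CE", "edema", "tumor", "whole_lesion"):
        out[f"flipped_{name}"] = flip_mask(out[name], axis=flip_axis)
    return RoiSet(masks=out)


def roi_set_from_labels(labels: np.ndarray, flip_axis: int = 0) -> RoiSet:
    """Build the ROI set from a phantom label volume."""
    labels = np.asarray(labels)
    return compose_rois(
        ce=labels == LABELS["CE"],
        necrosis=labels == LABELS["necrosis"],
        edema=labels == LABELS["edema"],
        gm=labels == LABELS["GM"],
        wm=labels == LABELS["WM"],
        flip_axis=flip_axis,
    )


def _map_volumes(maps) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Extract (metric -> volume) and a validity mask from a map container.

    Accepts fitted PerfusionMaps (uses their fit mask) or phantom TruthMaps
    (valid wherever labeled).
    """
    vols = {m: np.asarray(getattr(maps, m), dtype=float) for m in METRICS}
    if hasattr(maps, "mask"):
        valid = np.asarray(maps.mask, dtype=bool)
    elif hasattr(maps, "labels"):
        valid = np.asarray(maps.labels) > 0
    else:
        valid = np.ones(vols["mtt"].shape, dtype=bool)
    return vols, valid


def summarize_rois(maps, rois: RoiSet, subject: str = "subject") -> pd.DataFrame:
    """Unweighted per-ROI means of each perfusion map.

    Returns tidy rows (subject, roi, metric, value, n_voxels). An ROI that
    is empty or falls entirely outside the fit mask yields a missing value
    (NaN) rather than an error — some subjects genuinely lack a compartment.
    """
    vols, valid = _map_volumes(maps)
    rows = []
    for roi in rois.names():
        sel = rois[roi] & valid
        for metric in METRICS:
            vals = vols[metric][sel]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "subject": subject,
                    "roi": roi,
                    "metric": metric,
                    "value": float(vals.mean()) if vals.size else np.nan,
                    "n_voxels": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def cohort_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-subject ROI means into cohort rows.

    One output row per ROI × metric with the arithmetic mean, population
    standard deviation (ddof=0), min, max and subject count. Missing
    per-subject values are dropped; a group with no values is omitted. No
    rounding — use :func:`format_cohort_table` for presentation.
    """
    required = {"roi", "metric", "value"}
    if not required <= set(rows.columns):
        raise ValueError(f"rows need columns {sorted(required)}")
    data = rows.dropna(subset=["value"])
    if data.empty:
        return pd.DataFrame(columns=["roi", "metric", "mean", "sd", "min", "max", "n"])
    out = (
        data.groupby(["roi", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v)), min="min", max="max", n="count")
        .reset_index()
    )
    return out


def format_cohort_table(cohort: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation view: 'Mean (SD)' and 'Min-Max' strings per group."""
    view = cohort.copy()
    r = lambda x: f"{x:.{decimals}f}"
    view["mean_sd"] = [f"{r(m)} ({r(s)})" for m, s in zip(cohort["mean"], cohort["sd"])]
    view["min_max"] = [f"{r(lo)}-{r(hi)}" for lo, hi in zip(cohort["min"], cohort["max"])]
    return view[["roi", "metric", "mean_sd", "min_max", "n"]]


def compare_map_sets(maps_a, maps_b, rois: RoiSet) -> tuple[pd.DataFrame, dict]:
    """Paired per-ROI comparison of two co-registered map sets.

    Returns a table of (roi, metric, mean_a, mean_b, difference, ratio) and
    agreement statistics across all defined pairs: least-squares slope and
    intercept of mean_a vs mean_b, and the Pearson correlation.
    """
    vols_a, _ = _map_volumes(maps_a)
    vols_b, _ = _map_volumes(maps_b)
    if vols_a["mtt"].shape != vols_b["mtt"].shape:
        raise ValueError("map sets are on different grids")
    ta = summarize_rois(maps_a, rois, subject="A")
    tb = summarize_rois(maps_b, rois, subject="B")
    merged = ta.merge(tb, on=["roi", "metric"], suffixes=("_a", "_b"))
    table = pd.DataFrame(
        {
            "roi": merged["roi"],
            "metric": merged["metric"],
            "mean_a": merged["value_a"],
            "mean_b": merged["value_b"],
            "difference": merged["value_a"] - merged["value_b"],
            "ratio": merged["value_a"] / merged["value_b"],
        }
    )
    ok = table.dropna(subset=["mean_a", "mean_b"])
    a, b = ok["mean_a"].to_numpy(), ok["mean_b"].to_numpy()
    stats: dict[str, float] = {"n_pairs": int(len(ok))}
    if len(ok) >= 2 and np.ptp(b) > 0:
        slope, intercept = np.polyfit(b, a, 1)
        stats["slope"] = float(slope)
        stats["intercept"] = float(intercept)
        if np.ptp(a) > 0:
            stats["correlation"] = float(np.corrcoef(a, b)[0, 1])
    return table, stats
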