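"""ROI composition, flipped masks, cohort statistics, map-set comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dohbperf import (
    compare_map_sets,
    compose_rois,
    cohort_summary,
    flip_mask,
    roi_set_from_labels,
    summarize_rois,
)
from dohbperf.datasets import reference_ages, reference_cohort
from dohbperf.roi_analysis import format_cohort_table


class TestFlipMask:
    def test_involution(self):
        rng = np.random.default_rng(0)
        mask = rng.random((10, 8, 6)) > 0.5
        np.testing.assert_array_equal(flip_mask(flip_mask(mask)), mask)

    def test_symmetric_mask_is_fixed_point(self):
        mask = np.zeros((10, 8, 6), bool)
        mask[2] = mask[7] = True  # symmetric about the x mid-plane
        np.testing.assert_array_equal(flip_mask(mask), mask)

    def test_single_voxel_index_arithmetic(self):
        mask = np.zeros((20, 4, 4), bool)
        mask[3, 1, 2] = True
        flipped = flip_mask(mask)
        assert flipped[16, 1, 2]
        assert flipped.sum() == 1

    def test_voxel_count_preserved(self):
        rng = np.random.default_rng(1)
        mask = rng.random((9, 7, 5)) > 0.7
        assert flip_mask(mask).sum() == mask.sum()


class TestComposeRois:
    def _masks(self):
        shape = (10, 10, 4)
        ce = np.zeros(shape, bool)
        nec = np.zeros(shape, bool)
        ed = np.zeros(shape, bool)
        gm = np.zeros(shape, bool)
        wm = np.zeros(shape, bool)
        nec[7, 5, 2] = True
        ce[7, 4:7, 2] = True  # overlaps necrosis at y=5
        ed[7, 3:8, 2] = True
        gm[:, :, 2] = True
        wm[:, :, 1] = True
        return ce, nec, ed, gm, wm

    def test_overlap_resolves_to_necrosis(self):
        rois = compose_rois(*self._masks())
        assert rois["necrosis"][7, 5, 2]
        assert not rois["CE"][7, 5, 2]
        assert not rois["edema"][7, 4, 2]  # CE takes precedence over edema

    def test_lesion_partition_is_exact(self):
        rois = compose_rois(*self._masks())
        stack = rois["CE"].astype(int) + rois["necrosis"] + rois["edema"]
        assert stack.max() == 1
        np.testing.assert_array_equal(
            rois["whole_lesion"], rois["tumor"] | rois["edema"]
        )

    def test_empty_edema_makes_whole_lesion_equal_tumor(self):
        ce, nec, ed, gm, wm = self._masks()
        rois = compose_rois(ce, nec, np.zeros_like(ed), gm, wm)
        np.testing.assert_array_equal(rois["whole_lesion"], rois["tumor"])

    def test_gm_wm_exclude_whole_lesion(self):
        rois = compose_rois(*self._masks())
        assert not (rois["GM"] & rois["whole_lesion"]).any()
        assert not (rois["WM"] & rois["whole_lesion"]).any()

    def test_flipped_masks_attached_and_count_preserving(self):
        rois = compose_rois(*self._masks())
        for name in ("CE", "edema", "tumor", "whole_lesion"):
            assert rois[f"flipped_{name}"].sum() == rois[name].sum()

    def test_grid_mismatch_rejected(self):
        ce, nec, ed, gm, wm = self._masks()
        with pytest.raises(ValueError):
            compose_rois(ce, nec, ed, gm, np.zeros((3, 3, 3), bool))


class TestSummarizeRois:
    def test_constant_map_returns_the_constant(self, tiny_truth):
        rois = roi_set_from_labels(tiny_truth.labels)

        class Maps:
            mtt = np.full(tiny_truth.labels.shape, 4.5)
            rcbv = np.full(tiny_truth.labels.shape, 2.0)
            rcbf = np.full(tiny_truth.labels.shape, 13.3)
            mask = np.ones(tiny_truth.labels.shape, bool)

        table = summarize_rois(Maps(), rois)
        nonempty = table.dropna(subset=["value"])
        for metric, expected in (("mtt", 4.5), ("rcbv", 2.0), ("rcbf", 13.3)):
            vals = nonempty[nonempty.metric == metric]["value"]
            np.testing.assert_allclose(vals, expected)

    def test_truth_maps_give_compartment_parameters_exactly(self, tiny_truth, tiny_spec):
        rois = roi_set_from_labels(tiny_truth.labels)
        table = summarize_rois(tiny_truth, rois).set_index(["roi", "metric"])
        for roi in ("GM", "WM", "CE", "necrosis", "edema"):
            p = tiny_spec.compartments[roi]
            assert table.loc[(roi, "rcbv"), "value"] == pytest.approx(p.rcbv)
            assert table.loc[(roi, "mtt"), "value"] == pytest.approx(p.mtt)

    def test_roi_outside_fit_mask_is_missing(self, tiny_truth):
        rois = roi_set_from_labels(tiny_truth.labels)

        class Maps:
            mtt = np.full(tiny_truth.labels.shape, 1.0)
            rcbv = np.full(tiny_truth.labels.shape, 1.0)
            rcbf = np.full(tiny_truth.labels.shape, 1.0)
            mask = np.zeros(tiny_truth.labels.shape, bool)

        table = summarize_rois(Maps(), rois)
        assert table["value"].isna().all()
        assert (table["n_voxels"] == 0).all()


class TestCohortSummary:
    def test_reference_gm_mtt_row(self):
        cohort = cohort_summary(reference_cohort()).set_index(["roi", "metric"])
        row = cohort.loc[("GM", "mtt")]
        assert round(row["mean"], 1) == 3.5
        assert round(row["sd"], 1) == 1.1
        assert (row["min"], row["max"]) == (1.9, 5.6)
        assert row["n"] == 8

    def test_reference_ages(self):
        ages = reference_ages()
        stats = cohort_summary(
            pd.DataFrame({"roi": "cohort", "metric": "age", "value": ages.values})
        ).iloc[0]
        assert stats["mean"] == pytest.approx(56.0)
        assert round(stats["sd"], 1) == 13.8
        assert stats["n"] == 9

    def test_single_value_group(self):
        rows = pd.DataFrame(
            [{"subject": "s", "roi": "GM", "metric": "mtt", "value": 4.0}]
        )
        out = cohort_summary(rows).iloc[0]
        assert out["mean"] == 4.0
        assert out["sd"] == 0.0
        assert out["min"] == out["max"] == 4.0

    def test_missing_values_dropped_and_empty_group_omitted(self):
        rows = pd.DataFrame(
            [
                {"subject": "a", "roi": "CE", "metric": "mtt", "value": 2.0},
                {"subject": "b", "roi": "CE", "metric": "mtt", "value": np.nan},
                {"subject": "a", "roi": "edema", "metric": "mtt", "value": np.nan},
            ]
        )
        out = cohort_summary(rows)
        assert len(out) == 1
        assert out.iloc[0]["n"] == 1

    @settings(derandomize=True, max_examples=25)
    @given(perm_seed=st.integers(min_value=0, max_value=10_000))
    def test_permutation_invariance(self, perm_seed):
        rows = reference_cohort()
        shuffled = rows.sample(frac=1.0, random_state=perm_seed).reset_index(drop=True)
        a = cohort_summary(rows).sort_values(["roi", "metric"]).reset_index(drop=True)
        b = cohort_summary(shuffled).sort_values(["roi", "metric"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_presentation_formatting(self):
        cohort = cohort_summary(reference_cohort())
        view = format_cohort_table(cohort).set_index(["roi", "metric"])
        assert view.loc[("GM", "mtt"), "mean_sd"] == "3.5 (1.1)"
        assert view.loc[("WM", "rcbf"), "mean_sd"] == "42.6 (19.6)"


class TestCompareMapSets:
    def _maps(self, truth):
        class Maps:
            mtt = truth.mtt.copy()
            rcbv = truth.rcbv.copy()
            rcbf = truth.rcbf.copy()
            mask = truth.labels > 0

        return Maps()

    def test_identical_sets(self, tiny_truth):
        rois = roi_set_from_labels(tiny_truth.labels)
        table, stats = compare_map_sets(self._maps(tiny_truth), self._maps(tiny_truth), rois)
        ok = table.dropna(subset=["difference"])
        np.testing.assert_allclose(ok["difference"], 0.0)
        np.testing.assert_allclose(ok["ratio"], 1.0)
        assert stats["correlation"] == pytest.approx(1.0)

    def test_doubled_set_gives_slope_two(self, tiny_truth):
        a = self._maps(tiny_truth)
        b = self._maps(tiny_truth)
        for m in ("mtt", "rcbv", "rcbf"):
            setattr(a, m, 2.0 * getattr(a, m))
        table, stats = compare_map_sets(a, b, roi_set_from_labels(tiny_truth.labels))
        assert stats["slope"] == pytest.approx(2.0)
        assert stats["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_grid_mismatch_rejected(self, tiny_truth):
        a = self._maps(tiny_truth)

        class Small:
            mtt = np.ones((2, 2, 2))
            rcbv = np.ones((2, 2, 2))
            rcbf = np.ones((2, 2, 2))
            mask = np.ones((2, 2, 2), bool)

        with pytest.raises(ValueError):
            compare_map_sets(a, Small(), roi_set_from_labels(tiny_truth.labels))
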