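"""Compartment volumes, mean-centering, location, planes, histograms."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_bias, make_subject
from striocomp.metrics import (
    bias_histogram,
    location_stats,
    mean_center,
    plane_profile,
    summarize_volumes,
)
from striocomp.parcellation import classify, compute_bias, equal_volume_masks


def _summary_for(p_values):
    """Summary of a toy bias field on an all-striatal 2 mm grid."""
    p = np.asarray(p_values, float)
    bias = make_bias(p)
    labels = classify(bias)
    masks = equal_volume_masks(bias, volume_fraction=0.05)
    subj = make_subject(np.ones(p.shape + (10,), dtype=np.uint16))
    return summarize_volumes(bias, labels, masks, subj)


class TestSummarizeVolumes:
    def test_volume_is_count_times_voxel_volume(self):
        p = np.full((5, 5, 5), 0.2)
        p.ravel()[:10] = 0.9  # 10 striosome-like voxels of 8 mm^3
        summ = _summary_for(p)
        assert summ.vol_striosome_mm3 == pytest.approx(80.0)

    def test_relative_percentages_among_highly_biased(self):
        p = np.full((5, 5, 5), 0.5)
        p.ravel()[:12] = 0.90  # 12 highly biased striosome-like
        p.ravel()[12:100] = 0.10  # 88 highly biased matrix-like
        summ = _summary_for(p)
        assert summ.relative_striosome_pct == pytest.approx(12.0)
        assert summ.relative_matrix_pct == pytest.approx(88.0)
        assert summ.relative_striosome_pct + summ.relative_matrix_pct == 100.0

    def test_no_highly_biased_voxels_flagged_nan(self):
        summ = _summary_for(np.full((4, 4, 4), 0.5))
        assert np.isnan(summ.relative_striosome_pct)

    def test_volume_conservation_across_labels(self, small_subject):
        bias = compute_bias(small_subject)
        labels = classify(bias)
        masks = equal_volume_masks(bias)
        summ = summarize_volumes(bias, labels, masks, small_subject)
        labeled = (
            summ.vol_striosome_mm3
            + summ.vol_matrix_mm3
            + summ.vol_indeterminate_mm3
        )
        valid_vol = bias.valid_mask.sum() * bias.voxel_volume_mm3
        assert labeled == pytest.approx(valid_vol)

    def test_group_mean_relative_share_near_calibration(self, small_cohort):
        vals = []
        for s in small_cohort.subjects:
            bias = compute_bias(s)
            labels = classify(bias)
            masks = equal_volume_masks(bias)
            vals.append(
                summarize_volumes(bias, labels, masks, s).relative_striosome_pct
            )
        assert np.nanmean(vals) == pytest.approx(15.0, abs=1.5)


class TestMeanCenter:
    def test_constant_values_normalize_to_one(self):
        df = pd.DataFrame({"study_id": "A", "v": [2.0, 2.0, 2.0]})
        out = mean_center(df, ["v"])
        np.testing.assert_allclose(out["v_norm"], 1.0)
        np.testing.assert_allclose(out["v_pct"], 0.0)

    def test_two_point_normalization(self):
        df = pd.DataFrame({"study_id": "A", "v": [1.0, 3.0]})
        out = mean_center(df, ["v"])
        np.testing.assert_allclose(out["v_norm"], [0.5, 1.5])

    def test_study_means_are_one_exactly(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "study_id": np.repeat(["A", "B", "C"], 5),
                "v": rng.lognormal(size=15),
            }
        )
        out = mean_center(df, ["v"])
        for _, sub in out.groupby("study_id"):
            assert sub["v_norm"].mean() == pytest.approx(1.0)

    def test_zero_study_mean_rejected(self):
        df = pd.DataFrame({"study_id": "A", "v": [1.0, -1.0]})
        with pytest.raises(ValueError, match="zero study mean"):
            mean_center(df, ["v"])

    def test_single_subject_study_rejected(self):
        df = pd.DataFrame({"study_id": ["A"], "v": [1.0]})
        with pytest.raises(ValueError, match="at least 2"):
            mean_center(df, ["v"])


class TestLocationStats:
    def test_single_voxel_offset_and_rms(self):
        nucleus = np.zeros((7, 3, 3), dtype=bool)
        nucleus[:, 1, 1] = True  # centroid at x index 3
        comp = np.zeros_like(nucleus)
        comp[6, 1, 1] = True  # 3 voxels lateral at 1 mm spacing... use 1mm
        loc = location_stats(comp, nucleus, (1.0, 1.0, 1.0))
        assert loc.mean_offset_mm[0] == pytest.approx(3.0)
        assert loc.mean_offset_mm[1] == pytest.approx(0.0)
        assert loc.rms_distance_mm == pytest.approx(3.0)

    def test_symmetric_pair_cancels_mean_but_not_rms(self):
        nucleus = np.zeros((7, 3, 3), dtype=bool)
        nucleus[:, 1, 1] = True
        comp = np.zeros_like(nucleus)
        comp[1, 1, 1] = comp[5, 1, 1] = True  # +/- 2 mm
        loc = location_stats(comp, nucleus, (1.0, 1.0, 1.0))
        assert loc.mean_offset_mm[0] == pytest.approx(0.0)
        assert loc.rms_distance_mm == pytest.approx(2.0)

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(3)
        nucleus = rng.random((8, 8, 8)) > 0.4
        comp = nucleus & (rng.random((8, 8, 8)) > 0.6)
        voxel = (2.0, 1.5, 3.0)
        loc = location_stats(comp, nucleus, voxel)
        pts = (np.argwhere(comp & nucleus) + 0.5) * np.asarray(voxel)
        cen = (np.argwhere(nucleus) + 0.5).mean(axis=0) * np.asarray(voxel)
        rms = np.sqrt((((pts - cen) ** 2).sum(axis=1)).mean())
        assert loc.rms_distance_mm == pytest.approx(rms, abs=1e-9)
        np.testing.assert_allclose(loc.mean_offset_mm, (pts - cen).mean(axis=0),
                                   atol=1e-9)

    def test_centroid_voxel_has_zero_rms(self):
        nucleus = np.zeros((3, 3, 3), dtype=bool)
        nucleus[1, 1, 1] = True
        loc = location_stats(nucleus.copy(), nucleus, (2.0, 2.0, 2.0))
        assert loc.rms_distance_mm == 0.0

    def test_empty_compartment_flagged(self):
        nucleus = np.ones((2, 2, 2), dtype=bool)
        loc = location_stats(np.zeros_like(nucleus), nucleus, (1, 1, 1))
        assert loc.n_voxels == 0 and np.isnan(loc.rms_distance_mm)


class TestPlaneProfile:
    def test_single_slab_holds_all_volume(self):
        strio = np.zeros((4, 6, 4), dtype=bool)
        strio[:, 2, :] = True  # y in [4, 6) mm -> slab 2
        caud = np.zeros_like(strio)
        put = np.ones_like(strio)
        prof = plane_profile(strio, caud, put, (2.0, 2.0, 2.0), "left")
        put_prof = prof[prof.nucleus == "putamen"]
        nonzero = put_prof[put_prof.striosome_volume_mm3 > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["plane_index"] == 2
        assert nonzero.iloc[0]["striosome_volume_mm3"] == pytest.approx(16 * 8.0)

    def test_right_hemisphere_shifts_one_slab_rostral(self):
        strio = np.zeros((4, 6, 4), dtype=bool)
        strio[:, 2, :] = True
        caud = np.zeros_like(strio)
        put = np.ones_like(strio)
        left = plane_profile(strio, caud, put, (2.0, 2.0, 2.0), "left")
        right = plane_profile(strio, caud, put, (2.0, 2.0, 2.0), "right")
        li = left[left.striosome_volume_mm3 > 0].iloc[0]["plane_index"]
        ri = right[right.striosome_volume_mm3 > 0].iloc[0]["plane_index"]
        assert ri == li + 1

    def test_profile_sums_conserve_nucleus_volumes(self, small_subject):
        bias = compute_bias(small_subject)
        masks = equal_volume_masks(bias)
        prof = plane_profile(
            masks.striosome_like,
            small_subject.caudate_mask,
            small_subject.putamen_mask,
            small_subject.voxel_mm,
            "left",
        )
        vv = small_subject.voxel_volume_mm3
        for name, nucleus in (
            ("caudate", small_subject.caudate_mask),
            ("putamen", small_subject.putamen_mask),
        ):
            expected = (masks.striosome_like & nucleus).sum() * vv
            got = prof.loc[prof.nucleus == name, "striosome_volume_mm3"].sum()
            assert got == pytest.approx(expected)


class TestBiasHistogram:
    def test_bins_partition_the_restricted_volume(self, small_subject):
        bias = compute_bias(small_subject)
        hist = bias_histogram(bias, restriction=small_subject.putamen_mask)
        expected = (
            (small_subject.putamen_mask & bias.valid_mask).sum()
            * bias.voxel_volume_mm3
        )
        assert hist.total_mm3 == pytest.approx(expected)
        assert len(hist.volumes_mm3) == 50
        ranges = (
            hist.range_volume(0.55, 1.0)
            + hist.indeterminate_mm3
            + hist.range_volume(0.0, 0.45)
        )
        assert ranges == pytest.approx(hist.total_mm3)

    def test_uniform_bias_fills_bins_evenly(self):
        p = np.linspace(0.001, 0.999, 1000).reshape(10, 10, 10)
        hist = bias_histogram(make_bias(p))
        assert hist.volumes_mm3.min() >= 19 * 8.0
        assert hist.volumes_mm3.max() <= 21 * 8.0

    def test_endpoint_one_lands_in_last_bin(self):
        p = np.array([[[1.0, 0.0]]])
        hist = bias_histogram(make_bias(p))
        assert hist.volumes_mm3[-1] == pytest.approx(8.0)
        assert hist.volumes_mm3[0] == pytest.approx(8.0)

    def test_restriction_outside_striatum_rejected(self, small_subject):
        bias = compute_bias(small_subject)
        with pytest.raises(ValueError):
            bias_histogram(bias, restriction=~small_subject.striatal_mask)

    def test_depletion_shifts_high_bias_into_low_bias(self, small_spec):
        from striocomp.phantom import EffectSpec, generate_cohort

        cohort = generate_cohort(
            small_spec,
            EffectSpec(global_striosome_scale=0.6),
            [{"study_id": "A", "n_control": 4, "n_affected": 4}],
            master_seed=17,
        )
        sums = {"control": np.zeros(50), "anxiety": np.zeros(50)}
        for s in cohort.subjects:
            hist = bias_histogram(compute_bias(s), restriction=s.putamen_mask)
            sums[s.group] += hist.volumes_mm3
        # striosome-side high-bias bins lose volume; matrix-side bins gain
        high_s = slice(43, 50)  # p in [0.86, 1.0]
        low = slice(0, 8)  # p in [0, 0.16]
        assert sums["anxiety"][high_s].sum() < sums["control"][high_s].sum()
        assert sums["anxiety"][low].sum() > sums["control"][low].sum()
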