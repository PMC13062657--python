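"""Tissue generation, diffusion sampling, and cohort construction."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from conftest import SMALL_SPEC
from striocomp.phantom import (
    MATRIX,
    PUTAMEN,
    STRIOSOME,
    EffectSpec,
    PhantomSpec,
    TissueLabelGrid,
    bias_transfer,
    generate_cohort,
    generate_tissue,
    regenerate_cohort,
    sample_to_diffusion,
    simulate_subject,
)


class TestGenerateTissue:
    @pytest.mark.parametrize("seed", range(8))
    def test_fraction_calibrated_within_half_point(self, small_spec, seed):
        grid = generate_tissue(small_spec, seed=seed)
        assert abs(grid.striosome_fraction() - 0.15) <= 0.005

    def test_deterministic_under_fixed_seed(self, small_spec):
        a = generate_tissue(small_spec, seed=5)
        b = generate_tissue(small_spec, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.nucleus, b.nucleus)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.1])
    def test_degenerate_fraction_target_rejected(self, target):
        with pytest.raises(ValueError):
            PhantomSpec(striosome_fraction_target=target)

    def test_tubule_cap_must_fit_in_diffusion_voxel(self):
        with pytest.raises(ValueError):
            PhantomSpec(tubule_cap_mm=2.5, diffusion_voxel_mm=(2.0, 2.0, 2.0))

    def test_striosome_only_inside_nuclei(self, small_grid):
        strio = small_grid.labels == STRIOSOME
        assert not np.any(strio & (small_grid.nucleus == 0))

    def test_thickness_cap_enforced_to_grid_resolution(self, small_grid, small_spec):
        strio = small_grid.labels == STRIOSOME
        edt = ndimage.distance_transform_edt(strio, sampling=small_grid.voxel_mm)
        limit = small_spec.tubule_cap_mm / 2 + small_grid.voxel_mm / 2
        assert edt.max() <= limit + 1e-9


class TestSampleToDiffusion:
    def _toy_grid(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        nucleus = np.zeros_like(labels)
        # voxel (0,0,0): 8 striatal cells, 2 striosome -> fraction 0.25
        nucleus[:2, :2, :2] = 2
        labels[:2, :2, :2] = MATRIX
        labels[0, 0, :2] = STRIOSOME
        # voxel (1,0,0): all matrix -> fraction 0.0
        nucleus[2:, :2, :2] = 2
        labels[2:, :2, :2] = MATRIX
        # voxel (0,1,0): 3/8 striatal -> dropped by the 50% content rule
        nucleus[0, 2, 0] = 1
        nucleus[0, 3, 0] = 1
        nucleus[1, 2, 0] = 1
        labels[nucleus == 1] = MATRIX
        return TissueLabelGrid(labels, nucleus, "left", 1.0)

    def test_partial_volume_counting(self):
        spec = PhantomSpec(grid_shape_highres=(4, 4, 4))
        samp = sample_to_diffusion(self._toy_grid(), spec)
        assert samp.striosome_fraction[0, 0, 0] == pytest.approx(0.25)
        assert samp.striosome_fraction[1, 0, 0] == 0.0
        assert samp.striatal_mask[0, 0, 0] and samp.striatal_mask[1, 0, 0]
        assert not samp.striatal_mask[0, 1, 0]  # under 50% striatal content

    def test_masks_partition_striatum(self, small_grid, small_spec):
        samp = sample_to_diffusion(small_grid, small_spec)
        np.testing.assert_array_equal(
            samp.caudate_mask | samp.putamen_mask, samp.striatal_mask
        )
        assert not np.any(samp.caudate_mask & samp.putamen_mask)

    def test_weighted_mean_matches_highres_recount(self):
        spec = PhantomSpec()
        grid = generate_tissue(spec, seed=17)
        samp = sample_to_diffusion(grid, spec)
        # exact conservation over every voxel with striatal content
        has = samp.striatal_content > 0
        exact = np.average(
            samp.striosome_fraction[has].astype(float),
            weights=samp.striatal_content[has].astype(float),
        )
        assert exact == pytest.approx(grid.striosome_fraction(), abs=1e-6)
        # retained voxels only (50% edge rule) stay within a percentage point
        kept = np.average(
            samp.striosome_fraction[samp.striatal_mask].astype(float),
            weights=samp.striatal_content[samp.striatal_mask].astype(float),
        )
        assert kept == pytest.approx(grid.striosome_fraction(), abs=0.01)

    def test_rejects_finer_diffusion_than_highres(self, small_grid):
        spec = PhantomSpec(
            grid_shape_highres=(24, 28, 24),
            diffusion_voxel_mm=(0.5, 2.0, 2.0),
            tubule_cap_mm=1.9,
        )
        with pytest.raises(ValueError):
            sample_to_diffusion(small_grid, spec)


class TestBiasTransfer:
    def test_fixed_points_and_monotonicity(self):
        f = np.linspace(0, 1, 101)
        for gamma in (1.0, 2.0, 4.0):
            g = bias_transfer(f, gamma)
            assert g[0] == 0.0 and g[-1] == 1.0
            assert g[50] == pytest.approx(0.5)
            assert np.all(np.diff(g) >= 0)
        np.testing.assert_allclose(bias_transfer(f, 1.0), f, atol=1e-12)

    def test_complement_symmetry(self):
        f = np.linspace(0, 1, 51)
        g = bias_transfer(f, 4.0)
        np.testing.assert_allclose(g, 1.0 - bias_transfer(1.0 - f, 4.0), atol=1e-12)


class TestSimulateSubject:
    def test_counts_bounded_by_streamline_budget(self, small_subject):
        total = small_subject.counts.sum(axis=-1)
        assert total.max() <= small_subject.streamlines_per_voxel
        assert total[~small_subject.striatal_mask].max() == 0

    def test_full_reach_classifies_every_streamline(self, small_grid, small_spec):
        spec = dataclasses.replace(small_spec, reach_probability=1.0)
        subj = simulate_subject(
            small_grid, spec, EffectSpec(), subject_id="r1", seed=3
        )
        total = subj.counts.sum(axis=-1)
        assert np.all(total[subj.striatal_mask] == spec.streamlines_per_voxel)

    def test_balanced_voxel_split_follows_binomial_interval(self):
        # checkerboard tissue -> f = 0.5 in every voxel -> q_S = 0.5
        shape = (8, 8, 8)
        idx = np.indices(shape).sum(axis=0)
        labels = np.where(idx % 2 == 0, STRIOSOME, MATRIX).astype(np.uint8)
        nucleus = np.full(shape, PUTAMEN, dtype=np.uint8)
        grid = TissueLabelGrid(labels, nucleus, "left", 1.0)
        spec = PhantomSpec(grid_shape_highres=shape, reach_probability=1.0)
        subj = simulate_subject(grid, spec, EffectSpec(), subject_id="cb", seed=5)
        S = subj.counts[..., :5].sum(axis=-1).astype(float)
        M = subj.counts[..., 5:].sum(axis=-1).astype(float)
        p = (S / (S + M))[subj.striatal_mask]
        # sd of p at N=5000 is ~0.007; 0.5 +/- 0.02 is a ~3 sigma band
        assert np.mean(np.abs(p - 0.5) <= 0.02) >= 0.90

    def test_zone_scale_multiplies_true_bias(self, small_grid, small_spec):
        base = simulate_subject(
            small_grid, small_spec, EffectSpec(), subject_id="a", seed=9
        )
        scaled = simulate_subject(
            small_grid, small_spec, EffectSpec(rpz_bias_scale=0.859),
            subject_id="b", seed=9,
        )
        ratio = scaled.true_bias[base.true_bias > 0] / base.true_bias[
            base.true_bias > 0
        ]
        near_scaled = np.isclose(ratio, 0.859, atol=1e-5)
        near_unit = np.isclose(ratio, 1.0, atol=1e-5)
        assert np.all(near_scaled | near_unit)
        assert near_scaled.any() and near_unit.any()

    def test_depletion_removes_exact_tissue_share(self, small_grid, small_spec):
        base = simulate_subject(
            small_grid, small_spec, EffectSpec(), subject_id="a", seed=13
        )
        depl = simulate_subject(
            small_grid, small_spec, EffectSpec(global_striosome_scale=0.714),
            subject_id="b", seed=13,
        )
        def striosome_volume(s):
            m = s.striatal_mask
            return float(
                (
                    s.true_striosome_fraction[m].astype(float)
                    * s.striatal_content[m].astype(float)
                ).sum()
            )

        assert striosome_volume(depl) / striosome_volume(base) == pytest.approx(
            0.714, abs=0.005
        )


class TestLocationShift:
    def test_ground_truth_centroid_displaced(self):
        # oracle: recount the striosome centroid from ground-truth labels;
        # the putaminal displacement should be within one high-res voxel of
        # the requested shift on average
        spec = PhantomSpec()
        dx = []
        for seed in (301, 302, 303, 304):
            g0 = generate_tissue(spec, seed=seed)
            g1 = generate_tissue(spec, seed=seed, striosome_shift_mm=(1.3, 0, 0))
            dx.append(
                g1.striosome_centroid_mm(nucleus=PUTAMEN)[0]
                - g0.striosome_centroid_mm(nucleus=PUTAMEN)[0]
            )
        assert abs(np.mean(dx) - 1.3) <= spec.highres_voxel_mm
        assert np.mean(dx) > 0


class TestGenerateCohort:
    def test_single_subject_group_rejected(self, small_spec):
        with pytest.raises(ValueError, match="at least 2"):
            generate_cohort(
                small_spec, EffectSpec(),
                [{"study_id": "A", "n_control": 3, "n_affected": 1}],
            )

    def test_matched_pairs_need_controls(self, small_spec):
        with pytest.raises(ValueError, match="matched_pairs"):
            generate_cohort(
                small_spec, EffectSpec(),
                [{"study_id": "A", "n_control": 0, "n_affected": 2}],
                matched_pairs=True,
            )

    def test_covariate_table_schema(self, small_cohort):
        cov = small_cohort.covariates
        assert list(cov["group"].unique()) == ["control", "anxiety"]
        assert cov["subject_id"].is_unique
        assert len(cov) == 8

    def test_regeneration_from_manifest_is_identical(self, small_cohort):
        again = regenerate_cohort(small_cohort.manifest)
        for a, b in zip(small_cohort.subjects, again.subjects):
            np.testing.assert_array_equal(a.counts, b.counts)
            np.testing.assert_array_equal(a.fa, b.fa)
            assert a.subject_id == b.subject_id

    def test_matched_pairs_share_tissue_geometry(self, small_spec):
        cohort = generate_cohort(
            small_spec, EffectSpec(),
            [{"study_id": "A", "n_control": 2, "n_affected": 2}],
            master_seed=5, matched_pairs=True,
        )
        ctrl = [s for s in cohort.subjects if s.group == "control"]
        anx = [s for s in cohort.subjects if s.group == "anxiety"]
        for c, a in zip(ctrl, anx):
            np.testing.assert_array_equal(
                c.true_striosome_fraction, a.true_striosome_fraction
            )
            assert not np.array_equal(c.counts, a.counts)  # independent noise

    def test_null_effect_groups_share_bias_distribution(self, small_spec):
        from scipy.stats import ks_2samp

        rejections = 0
        for rep in range(5):
            cohort = generate_cohort(
                small_spec, EffectSpec(),
                [{"study_id": "A", "n_control": 4, "n_affected": 4}],
                master_seed=100 + rep,
            )
            pooled = {"control": [], "anxiety": []}
            for s in cohort.subjects:
                pooled[s.group].append(s.true_bias[s.striatal_mask])
            stat = ks_2samp(
                np.concatenate(pooled["control"]), np.concatenate(pooled["anxiety"])
            )
            rejections += stat.pvalue < 0.01
        assert rejections <= 1
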