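"""Desk-scale simulation experiments at the study's stated conditions.

Each experiment injects one of the published effect sizes into a phantom
cohort and recovers it end-to-end through the pipeline: global striosome
depletion through parcellation + high-bias volumes, the zone-restricted
bias reduction through zone means, the lateral location shift through
location statistics, the FA tissue contrast through equal-volume-mask
diffusivity, tissue-fraction calibration by direct recount, and the
family-wise error rate of the voxelwise permutation test under a global
null.  The same entry points drive both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import location_stats, mean_center, summarize_volumes
from .parcellation import classify, compute_bias, equal_volume_masks
from .phantom import (
    EffectSpec,
    PhantomSpec,
    generate_cohort,
    generate_tissue,
    true_zone_mask,
)
from .regional import group_percent_difference, rpz_means
from .voxelwise import permutation_test

#: reduced-geometry phantom for replicate-heavy experiments (the null
#: family-wise-error study runs hundreds of cohorts)
SMALL_SPEC = PhantomSpec(grid_shape_highres=(24, 28, 24))


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def recover_global_depletion(
    seed: int,
    n_per_group: int = 30,
    scale: float = 0.714,
    spec: PhantomSpec | None = None,
) -> dict:
    """Percent reduction of group-mean highly biased striosome-like volume.

    The affected group's striosome tissue volume is scaled by ``scale``
    (patchy depletion); the pipeline (bias -> classification -> volumes)
    recovers the reduction in highly biased (p >= 0.87) striosome-like
    volume relative to controls.
    """
    spec = spec or PhantomSpec()
    effect = EffectSpec(global_striosome_scale=scale)
    cohort = generate_cohort(
        spec,
        effect,
        [{"study_id": "A", "n_control": n_per_group, "n_affected": n_per_group}],
        master_seed=_derive_seed(seed, 2),
    )
    vols = {"control": [], "anxiety": []}
    for s in cohort.subjects:
        bias = compute_bias(s)
        labels = classify(bias)
        masks = equal_volume_masks(bias)
        summ = summarize_volumes(bias, labels, masks, s)
        vols[s.group].append(summ.vol_high_striosome_mm3)
    control = float(np.mean(vols["control"]))
    affected = float(np.mean(vols["anxiety"]))
    return {
        "percent_reduction": (control - affected) / control * 100.0,
        "control_mean_mm3": control,
        "affected_mean_mm3": affected,
        "n": n_per_group,
    }


def recover_zone_bias_reduction(
    seed: int,
    n_per_group: int = 30,
    scale: float = 0.859,
    spec: PhantomSpec | None = None,
) -> dict:
    """Percent reduction of mean striosome-like bias inside the zone.

    The generator multiplies the striosome-side connection probability by
    ``scale`` inside the designated rostral-putamen zone for affected
    subjects (matched control:affected design, mirroring the study's direct
    matching); recovery is the group percent difference of per-subject zone
    means.
    """
    spec = spec or PhantomSpec()
    effect = EffectSpec(rpz_bias_scale=scale)
    cohort = generate_cohort(
        spec,
        effect,
        [{"study_id": "A", "n_control": n_per_group, "n_affected": n_per_group}],
        master_seed=_derive_seed(seed, 3),
        matched_pairs=True,
    )
    ref = cohort.subjects[0]
    zone = true_zone_mask(spec, effect, ref.striatal_mask.shape, ref.voxel_mm)
    zone &= ref.striatal_mask
    maps = [compute_bias(s) for s in cohort.subjects]
    table = rpz_means(maps, zone, ref.striatal_mask)
    table["group"] = [s.group for s in cohort.subjects]
    pct, ttest = group_percent_difference(table["mean_in_rpz"], table["group"])
    return {
        "percent_reduction": float(pct),
        "p_value": ttest.p,
        "n": n_per_group,
    }


def calibration_fractions(seed: int, n_seeds: int = 10,
                          spec: PhantomSpec | None = None) -> dict:
    """Achieved striosome tissue percentage over independent phantoms."""
    spec = spec or PhantomSpec()
    seeds = np.random.SeedSequence([seed, 4]).generate_state(n_seeds) % (2**31)
    pcts = [
        generate_tissue(spec, seed=int(s)).striosome_fraction() * 100.0
        for s in seeds
    ]
    return {
        "achieved_pct": pcts,
        "mean_pct": float(np.mean(pcts)),
        "target_pct": spec.striosome_fraction_target * 100.0,
        "n": n_seeds,
    }


def _matrix_bias_stack(cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, X, Y, Z) matrix-side bias stack and the common valid mask."""
    maps = [compute_bias(s) for s in cohort.subjects]
    valid = np.logical_and.reduce([b.valid_mask for b in maps])
    stack = np.stack([np.where(valid, b.p_matrix, 0.0) for b in maps])
    groups = np.array([s.group for s in cohort.subjects])
    return stack, valid, groups


def null_fwe_rate(
    seed: int,
    n_cohorts: int = 200,
    n_per_group: int = 10,
    n_perm: int = 500,
    alpha: float = 0.05,
    spec: PhantomSpec | None = None,
) -> dict:
    """Empirical FWE of the voxelwise test under a global null.

    ``n_cohorts`` independent no-effect cohorts are simulated (reduced
    phantom geometry for tractability) and tested; the reported rate is the
    fraction with any FWE-significant voxel, alongside its Monte Carlo
    standard error.
    """
    spec = spec or SMALL_SPEC
    effect = EffectSpec()
    hits = 0
    for i in range(n_cohorts):
        cohort = generate_cohort(
            spec,
            effect,
            [{"study_id": "A", "n_control": n_per_group,
              "n_affected": n_per_group}],
            master_seed=_derive_seed(seed, 1000 + i),
        )
        stack, valid, groups = _matrix_bias_stack(cohort)
        res = permutation_test(
            stack,
            groups,
            valid,
            voxel_mm=cohort.subjects[0].voxel_mm,
            n_perm=n_perm,
            alpha=alpha,
            seed=_derive_seed(seed, 5000 + i),
        )
        hits += int(res.significant_mask.any())
    rate = hits / n_cohorts
    return {
        "fwe_rate": rate,
        "alpha": alpha,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_cohorts)),
        "n": n_cohorts,
    }


def recover_location_shift(
    seed: int,
    n_per_group: int = 30,
    shift_mm: float = 1.3,
    spec: PhantomSpec | None = None,
) -> dict:
    """Group difference in mean lateral offset of striosome-like voxels.

    The affected group's putaminal striosome distribution is displaced
    ``shift_mm`` laterally (matched design); parcellation plus location
    statistics recover the between-group difference in mean lateral (x)
    offset from the putamen centroid.  Both hemispheres are parcellated
    independently and the per-subject offsets averaged, as in per-hemisphere
    location analyses.
    """
    spec = spec or PhantomSpec()
    effect = EffectSpec(location_shift_mm=(shift_mm, 0.0, 0.0))
    diffs = []
    for stream, hemi in ((6, "left"), (8, "right")):
        cohort = generate_cohort(
            spec,
            effect,
            [{"study_id": "A", "n_control": n_per_group,
              "n_affected": n_per_group}],
            master_seed=_derive_seed(seed, stream),
            matched_pairs=True,
            hemisphere=hemi,
        )
        offs = {"control": [], "anxiety": []}
        for s in cohort.subjects:
            bias = compute_bias(s)
            masks = equal_volume_masks(bias)
            loc = location_stats(
                masks.striosome_like, s.putamen_mask, s.voxel_mm,
                "putamen", "striosome",
            )
            offs[s.group].append(loc.mean_offset_mm[0])
        diffs.append(float(np.mean(offs["anxiety"]) - np.mean(offs["control"])))
    return {"lateral_shift_mm": float(np.mean(diffs)), "n": n_per_group}


def recover_fa_contrast(
    seed: int,
    n_subjects: int = 40,
    spec: PhantomSpec | None = None,
) -> dict:
    """Percent FA elevation in striosome-like over matrix-like voxels.

    A two-study cohort (no group effects; the FA contrast is a tissue
    property of every subject) is parcellated, FA is averaged within the
    equal-volume masks, mean-centered within study against whole-striatum
    FA, and the percent elevation of the striosome-like mask is recovered.
    """
    spec = spec or PhantomSpec()
    effect = EffectSpec()
    half = n_subjects // 2
    cohort = generate_cohort(
        spec,
        effect,
        [
            {"study_id": "A", "n_control": half},
            {"study_id": "B", "n_control": n_subjects - half},
        ],
        master_seed=_derive_seed(seed, 7),
    )
    rows = []
    for s in cohort.subjects:
        bias = compute_bias(s)
        labels = classify(bias)
        masks = equal_volume_masks(bias)
        summ = summarize_volumes(bias, labels, masks, s)
        rows.append(
            {
                "subject_id": s.subject_id,
                "study_id": s.study_id,
                "fa_striosome": summ.fa_striosome,
                "fa_matrix": summ.fa_matrix,
                "fa_striatum": summ.fa_striatum,
            }
        )
    df = pd.DataFrame(rows)
    df = mean_center(
        df, ["fa_striosome", "fa_matrix"], reference_col="fa_striatum"
    )
    elevation = (
        df["fa_striosome_norm"].mean() / df["fa_matrix_norm"].mean() - 1.0
    ) * 100.0
    return {"fa_elevation_pct": float(elevation), "n": n_subjects}
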