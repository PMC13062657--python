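"""End-to-end experiment runner.

Executes the full analysis sequence on a simulated cohort: simulate ->
parcellate (full and leave-one-out) -> compartment metrics -> voxelwise
permutation test -> zone analyses -> bait-region contributions -> stats
tables, and writes a versioned report bundle (CSV tables, NIfTI maps, JSON
summary) whose every output traces back to the config hash and master seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .loo import bait_bias_table, composite_bait_sums, rpz_contribution_table
from .metrics import bias_histogram, mean_center, plane_profile, summarize_volumes
from .parcellation import classify, compute_bias, equal_volume_masks
from .phantom import EffectSpec, PhantomSpec, generate_cohort
from .regional import group_percent_difference, rpz_means, seeded_ratios
from .stats_core import bh_fdr, one_sample_t, unpaired_t
from .voxelwise import permutation_test

log = logging.getLogger("striocomp")

DEFAULT_CONFIG = {
    "spec": {},
    "effect": {},
    "design": [{"study_id": "A", "n_control": 8, "n_affected": 8}],
    "master_seed": 0,
    "matched_pairs": False,
    "n_perm": 500,
    "alpha": 0.05,
    "volume_fraction": 0.0668,
    "write_volumes": False,
}


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _stage_durations(stamps: dict[str, float]) -> dict[str, float]:
    names = list(stamps)
    out = {}
    for i, name in enumerate(names):
        end = stamps[names[i + 1]] if i + 1 < len(names) else time.time()
        out[name] = round(end - stamps[name], 3)
    return out


def run_experiment(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the full pipeline per ``config`` and write the report bundle.

    Deterministic given the config and master seed; ``seed`` overrides the
    config's master seed.  Returns the JSON-ready summary dictionary.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    if seed is not None:
        cfg["master_seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = sio.config_hash(cfg)
    stamps: dict[str, float] = {}

    def stage(name):
        stamps[name] = time.time()
        log.info("stage %s", name)

    spec = PhantomSpec(**_tuplify(cfg["spec"]))
    effect = EffectSpec(**_tuplify(cfg["effect"]))

    stage("simulate")
    cohort = generate_cohort(
        spec,
        effect,
        cfg["design"],
        master_seed=cfg["master_seed"],
        matched_pairs=cfg["matched_pairs"],
    )
    sio.write_covariates(cohort.covariates, out / "covariates.csv")
    sio.dump_manifest(
        {"config_hash": chash, **cohort.manifest}, out / "manifest.json"
    )
    if cfg["write_volumes"]:
        for s in cohort.subjects:
            sio.write_subject(s, out / "subjects" / s.subject_id)

    stage("parcellate")
    vf = cfg["volume_fraction"]
    biases, labelmaps, maskpairs, summaries = [], [], [], []
    for s in cohort.subjects:
        b = compute_bias(s)
        lab = classify(b)
        m = equal_volume_masks(b, volume_fraction=vf)
        biases.append(b)
        labelmaps.append(lab)
        maskpairs.append(m)
        summaries.append(summarize_volumes(b, lab, m, s))
        log.info(
            "parcellated %s: thresholds strio %.2f matrix %.2f target %d",
            s.subject_id, m.threshold_striosome, m.threshold_matrix,
            m.target_voxel_count,
        )

    stage("metrics")
    summary_df = pd.DataFrame([vars(x) for x in summaries])
    summary_df = mean_center(
        summary_df,
        ["fa_striosome", "fa_matrix", "rd_striosome", "rd_matrix"],
        reference_col="fa_striatum",
    )
    summary_df.to_csv(out / "compartment_summaries.csv", index=False)
    profiles = pd.concat(
        [
            plane_profile(
                m.striosome_like, s.caudate_mask, s.putamen_mask, s.voxel_mm,
                s.hemisphere,
            ).assign(subject_id=s.subject_id, group=s.group)
            for s, m in zip(cohort.subjects, maskpairs)
        ]
    )
    profiles.to_csv(out / "plane_profiles.csv", index=False)
    hist_rows = []
    for s, b in zip(cohort.subjects, biases):
        hist = bias_histogram(b, restriction=s.putamen_mask)
        for lo, hi, v in zip(hist.edges[:-1], hist.edges[1:], hist.volumes_mm3):
            hist_rows.append(
                {"subject_id": s.subject_id, "group": s.group,
                 "bin_lo": lo, "bin_hi": hi, "volume_mm3": v}
            )
    pd.DataFrame(hist_rows).to_csv(out / "bias_histograms.csv", index=False)

    stage("voxelwise")
    valid = np.logical_and.reduce([b.valid_mask for b in biases])
    stack = np.stack([np.where(valid, b.p_matrix, 0.0) for b in biases])
    groups = np.array([s.group for s in cohort.subjects])
    ref = cohort.subjects[0]
    result = permutation_test(
        stack, groups, valid, voxel_mm=ref.voxel_mm,
        n_perm=cfg["n_perm"], alpha=cfg["alpha"], seed=cfg["master_seed"],
    )
    aff = ref.affine
    sio.write_volume(result.t_map, aff, out / "tstat.nii")
    sio.write_volume(result.tfce_map, aff, out / "tfce.nii")
    sio.write_volume(result.fwe_p_map, aff, out / "fwe_p.nii")
    sio.write_volume(1.0 - result.fwe_p_map, aff, out / "fwe_1minusp.nii")
    sio.write_volume(result.significant_mask, aff, out / "significant.nii")
    sio.write_volume(result.rpz_mask, aff, out / "rpz.nii")

    stage("regional")
    regional: dict = {"rpz_empty": result.rpz_empty}
    if not result.rpz_empty:
        table = rpz_means(biases, result.rpz_mask, ref.striatal_mask)
        table["group"] = groups
        table.to_csv(out / "rpz_means.csv", index=False)
        pct, tt = group_percent_difference(table["mean_in_rpz"], table["group"])
        regional["rpz_percent_difference"] = pct
        regional["rpz_t"] = tt.t
        regional["rpz_p"] = tt.p
        ratios = seeded_ratios(cohort.subjects, result.rpz_mask)
        ratios.to_csv(out / "seeded_ratios.csv", index=False)

    stage("loo")
    bait = bait_bias_table(cohort.subjects, volume_fraction=vf)
    bait.to_csv(out / "bait_bias.csv", index=False)
    composite_bait_sums(bait).to_csv(out / "bait_composites.csv", index=False)
    loo_stats = {}
    if not result.rpz_empty:
        contrib = rpz_contribution_table(cohort.subjects, result.rpz_mask)
        contrib.to_csv(out / "rpz_contributions.csv", index=False)
        ps = []
        for region, sub in contrib.groupby("region"):
            tt = unpaired_t(
                sub.loc[sub.group == "control", "mean_in_rpz"],
                sub.loc[sub.group != "control", "mean_in_rpz"],
            )
            ps.append({"region": region, "t": tt.t, "p": tt.p})
        fam = pd.DataFrame(ps)
        fdr = bh_fdr(fam["p"].to_numpy())
        fam["reject_fdr"] = fdr.reject
        fam.to_csv(out / "rpz_contribution_tests.csv", index=False)
        loo_stats["fdr_threshold"] = fdr.threshold

    stage("stats")
    rel = summary_df["relative_striosome_pct"].dropna()
    hist_t = one_sample_t(rel) if len(rel) >= 2 else None
    groups_ctrl = summary_df["group"] == "control"
    vol_t = unpaired_t(
        summary_df.loc[groups_ctrl, "vol_high_striosome_mm3"],
        summary_df.loc[~groups_ctrl, "vol_high_striosome_mm3"],
    ) if (~groups_ctrl).any() else None

    summary = {
        "config_hash": chash,
        "master_seed": cfg["master_seed"],
        "n_subjects": len(cohort.subjects),
        "stage_wall_times": _stage_durations(stamps),
        "voxelwise": {
            "n_significant": int(result.significant_mask.sum()),
            "rpz_voxels": int(result.rpz_mask.sum()),
            "exact": result.exact,
            "n_permutations": result.n_permutations,
        },
        "regional": regional,
        "loo": loo_stats,
        "relative_striosome_vs_histology": (
            {"t": hist_t.t, "p": hist_t.p} if hist_t else None
        ),
        "high_bias_striosome_volume_t": (
            {"t": vol_t.t, "p": vol_t.p} if vol_t else None
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
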