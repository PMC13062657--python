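"""Leave-one-out (N-1) parcellation and bait-region contributions.

Re-parcellating with nine bait regions lets the tenth be evaluated against
compartment masks it did not help define (the circularity guard: a region
cannot both define striosome-like voxels and then be found highly connected
to them).  The module quantifies each region's compartment-biased
connectivity against the N-1 masks and its contribution to zone bias via
full-minus-N-1 difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation import BiasMap, CompartmentMasks, compute_bias, equal_volume_masks
from .phantom import SubjectConnectivity
from .regions import ALL_REGIONS, favored_compartment


@dataclass
class RegionContribution:
    region: str
    subject_id: str
    n_minus_one_bias: BiasMap
    difference_map: np.ndarray  # full-10-region bias minus N-1 bias
    mean_in_rpz: float


def loo_parcellation(
    subject: SubjectConnectivity,
    left_out: str,
    volume_fraction: float = 0.0668,
    step: float = 0.01,
) -> tuple[BiasMap, CompartmentMasks]:
    """Parcellation from the nine regions that exclude ``left_out``."""
    if left_out not in ALL_REGIONS:
        raise ValueError(f"unknown bait region {left_out!r}")
    regions = tuple(r for r in subject.region_names if r != left_out)
    bias = compute_bias(subject, regions)
    masks = equal_volume_masks(bias, volume_fraction=volume_fraction, step=step)
    return bias, masks


def bait_bias_fraction(
    subject: SubjectConnectivity, left_out: str, masks: CompartmentMasks
) -> float:
    """Share of the left-out region's mask-directed counts reaching its target.

    With the N-1 compartment masks as targets, the statistic is the region's
    summed counts into its nominal target compartment divided by its counts
    into both masks (pooled over striatal voxels; phantom bait regions have
    no voxel extent of their own).  NaN when the region reaches neither
    mask (subject excluded from that region's statistic).
    """
    c = subject.counts_for([left_out])[..., 0].astype(float)
    target = favored_compartment(left_out)
    into_s = float(c[masks.striosome_like].sum())
    into_m = float(c[masks.matrix_like].sum())
    if into_s + into_m == 0:
        return float("nan")
    hit = into_s if target == "striosome" else into_m
    return hit / (into_s + into_m)


def bait_bias_table(
    subjects: list[SubjectConnectivity],
    volume_fraction: float = 0.0668,
) -> pd.DataFrame:
    """Mean-centered biased-connectivity statistic per region and subject.

    Each region's statistic comes from that subject's own N-1 parcellation;
    mean-centering across the whole cohort (all groups pooled) per region
    removes between-region scale differences, and the five mean-centered
    values of each composite are summed per subject.
    """
    rows = []
    for s in subjects:
        for region in ALL_REGIONS:
            _, masks = loo_parcellation(s, region, volume_fraction=volume_fraction)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "region": region,
                    "target": favored_compartment(region),
                    "biased_fraction": bait_bias_fraction(s, region, masks),
                }
            )
    df = pd.DataFrame(rows)
    df["mean_centered"] = df.groupby("region")["biased_fraction"].transform(
        lambda v: v / v.mean()
    )
    return df


def composite_bait_sums(bait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject sum of mean-centered values over each composite."""
    return (
        bait_table.groupby(["subject_id", "group", "target"], observed=True)[
            "mean_centered"
        ]
        .sum()
        .unstack("target")
        .rename(columns=lambda c: f"{c}_composite")
        .reset_index()
    )


def region_contribution_in_rpz(
    subject: SubjectConnectivity,
    region: str,
    rpz_mask: np.ndarray,
    full_bias: BiasMap | None = None,
) -> RegionContribution:
    """Full-minus-N-1 bias difference, averaged over the RPZ.

    The difference map isolates what the left-out region contributed to
    striosome-side bias; it is identically zero wherever the region has no
    counts.  Voxels valid in only one of the two maps are excluded.
    """
    if full_bias is None:
        full_bias = compute_bias(subject)
    n1_bias, _ = loo_parcellation(subject, region)
    both = full_bias.valid_mask & n1_bias.valid_mask
    diff = np.zeros(full_bias.p_striosome.shape)
    diff[both] = full_bias.p_striosome[both] - n1_bias.p_striosome[both]
    sel = rpz_mask & both
    mean_rpz = float(diff[sel].mean()) if sel.any() else float("nan")
    return RegionContribution(
        region=region,
        subject_id=subject.subject_id,
        n_minus_one_bias=n1_bias,
        difference_map=diff,
        mean_in_rpz=mean_rpz,
    )


def rpz_contribution_table(
    subjects: list[SubjectConnectivity], rpz_mask: np.ndarray
) -> pd.DataFrame:
    """Per-subject, per-region mean difference-map value within the RPZ."""
    rows = []
    for s in subjects:
        full = compute_bias(s)
        for region in ALL_REGIONS:
            contrib = region_contribution_in_rpz(s, region, rpz_mask, full_bias=full)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "region": region,
                    "mean_in_rpz": contrib.mean_in_rpz,
                }
            )
    return pd.DataFrame(rows)
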