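"""Zone-centric analyses and anxiety-severity handling.

Mean compartment bias inside and outside the RPZ, composite seeded-count
ratios (RPZ:non-RPZ and matrix-favoring:striosome-favoring), categorization
of anxiety-instrument total scores, and the severity-covaried ANOVA of
zone connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parcellation import BiasMap
from .phantom import SubjectConnectivity
from .regions import MATRIX_FAVORING, STRIOSOME_FAVORING
from .stats_core import AnovaResult, TTestResult, severity_anova, unpaired_t

#: canonical low-to-high ordering across all three instruments' labels
SEVERITY_ORDER = ("none", "minimal", "mild", "moderate", "high", "severe")

# Published total-score cutoffs per instrument.  The printed GAD-7 and STAI
# ranges overlap at their boundaries; a score claimed by two ranges goes to
# the more severe category (documented tie rule), which the (lo, hi)
# intervals below already encode.
_CUTOFFS = {
    "GAD7": [(0, 4, "none"), (5, 5, "mild"), (6, 9, "moderate"), (10, 21, "severe")],
    "BAI": [(0, 7, "minimal"), (8, 15, "mild"), (16, 25, "moderate"), (26, 63, "high")],
    "STAI": [(20, 37, "none"), (38, 43, "moderate"), (44, 80, "high")],
}


def severity_category(score: float, instrument: str) -> str:
    """Map an anxiety-instrument total score to its severity category."""
    try:
        table = _CUTOFFS[instrument.upper().replace("-", "")]
    except KeyError:
        raise ValueError(f"unknown instrument {instrument!r}") from None
    for lo, hi, cat in table:
        if lo <= score <= hi:
            return cat
    lo = table[0][0]
    hi = table[-1][1]
    raise ValueError(f"{instrument} score {score} outside range [{lo}, {hi}]")


def rpz_means(
    bias_maps: list[BiasMap], rpz_mask: np.ndarray, striatal_mask: np.ndarray
) -> pd.DataFrame:
    """Per-subject mean striosome-side bias inside and outside the RPZ."""
    if not rpz_mask.any():
        raise ValueError("empty RPZ mask")
    if np.any(rpz_mask & ~striatal_mask):
        raise ValueError("RPZ mask must lie within the striatal mask")
    outside = striatal_mask & ~rpz_mask
    rows = []
    for b in bias_maps:
        rows.append(
            {
                "subject_id": b.subject_id,
                "hemisphere": b.hemisphere,
                "mean_in_rpz": float(np.nanmean(b.p_striosome[rpz_mask])),
                "mean_outside_rpz": float(np.nanmean(b.p_striosome[outside])),
                "mean_striatum": float(np.nanmean(b.p_striosome[striatal_mask])),
            }
        )
    return pd.DataFrame(rows)


def group_percent_difference(
    values: pd.Series, groups: pd.Series, control: str = "control"
) -> tuple[float, TTestResult]:
    """(control - affected) / control x 100 with a one-tailed unpaired t.

    The declared direction follows the whole-striatum pattern (control above
    affected), per the one-tailed zone comparisons.
    """
    is_ctrl = groups == control
    c = values[is_ctrl].to_numpy(float)
    a = values[~is_ctrl].to_numpy(float)
    pct = (c.mean() - a.mean()) / c.mean() * 100.0
    return pct, unpaired_t(c, a, tails=1, direction="a>b")


def seeded_ratios(
    subjects: list[SubjectConnectivity], rpz_mask: np.ndarray
) -> pd.DataFrame:
    """Composite count ratios per subject: RPZ:non-RPZ and MF:SF.

    For each composite (matrix-favoring, striosome-favoring), the ratio of
    summed counts reaching RPZ vs non-RPZ striatum; and within each zone the
    matrix-favoring : striosome-favoring ratio.  Zero denominators yield
    NaN (flagged undefined) rather than an error.
    """
    rows = []
    for s in subjects:
        nonrpz = s.striatal_mask & ~rpz_mask
        sums = {}
        for comp, names in (("sf", STRIOSOME_FAVORING), ("mf", MATRIX_FAVORING)):
            c = s.counts_for(names).sum(axis=-1).astype(float)
            sums[comp, "rpz"] = float(c[rpz_mask & s.striatal_mask].sum())
            sums[comp, "nonrpz"] = float(c[nonrpz].sum())

        def ratio(num, den):
            return num / den if den > 0 else float("nan")

        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "mf_rpz_to_nonrpz": ratio(sums["mf", "rpz"], sums["mf", "nonrpz"]),
                "sf_rpz_to_nonrpz": ratio(sums["sf", "rpz"], sums["sf", "nonrpz"]),
                "mf_to_sf_in_rpz": ratio(sums["mf", "rpz"], sums["sf", "rpz"]),
                "mf_to_sf_outside_rpz": ratio(
                    sums["mf", "nonrpz"], sums["sf", "nonrpz"]
                ),
            }
        )
    return pd.DataFrame(rows)


def rpz_severity_anova(
    rpz_table: pd.DataFrame,
    covariates: pd.DataFrame,
    value_col: str = "mean_in_rpz",
) -> AnovaResult:
    """ANOVA of zone striosome-like bias on severity with study nuisance.

    Controls enter as their own (lowest) category; severity categories are
    ordered along ``SEVERITY_ORDER``.
    """
    df = rpz_table.merge(covariates, on="subject_id")
    sev = df["severity_category"].fillna("none")
    order = [c for c in SEVERITY_ORDER if c in set(sev)]
    return severity_anova(df[value_col], sev, df["study_id"], order=order)
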