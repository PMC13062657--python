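"""Shared statistical kernels: t-tests, ANOVA, Benjamini-Hochberg FDR.

Thin, convention-fixing wrappers over scipy/statsmodels.  Degenerate inputs
(zero variance) follow explicit conventions instead of propagating NaNs:
equal means with zero variance give p = 1; unequal means give p = 0 with a
``degenerate`` flag.  FDR families are always an explicit argument of the
caller — a family is whatever p-values are passed in together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

#: histologic striosome share of striatal volume, percent (15:85 ratio)
HISTOLOGIC_STRIOSOME_PCT = 15.0


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``."""
    return (value - reference) / reference * 100.0


def unpaired_t(a, b, tails: int = 2, equal_var: bool = True,
               direction: str = "a>b") -> TTestResult:
    """Unpaired t-test (pooled-variance by default; Welch via flag).

    For ``tails=1`` the caller must declare the tested direction
    (``"a>b"`` or ``"a<b"``); the one-tailed p is halved when the observed
    difference points the declared way and ``1 - p/2`` otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if direction not in ("a>b", "a<b"):
        raise ValueError("direction must be 'a>b' or 'a<b'")

    df = a.size + b.size - 2 if equal_var else np.nan
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0.0 and sb == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(df), 1.0, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * np.inf, float(df), 0.0, degenerate=True)

    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    if not equal_var:
        df = float(res.df)
    p = float(res.pvalue)
    if tails == 1:
        points_declared = (t > 0) == (direction == "a>b") or t == 0
        p = p / 2.0 if points_declared else 1.0 - p / 2.0
    return TTestResult(t, float(df), p)


def one_sample_t(values, reference: float = HISTOLOGIC_STRIOSOME_PCT) -> TTestResult:
    """One-sample t-test of a mean against a reference value."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if values.std(ddof=1) == 0.0:
        if values.mean() == reference:
            return TTestResult(0.0, float(values.size - 1), 1.0, degenerate=True)
        sign = 1.0 if values.mean() > reference else -1.0
        return TTestResult(sign * np.inf, float(values.size - 1), 0.0, degenerate=True)
    res = stats.ttest_1samp(values, reference)
    return TTestResult(float(res.statistic), float(values.size - 1), float(res.pvalue))


@dataclass(frozen=True)
class FdrResult:
    reject: np.ndarray  # boolean, in input order
    threshold: float  # data-dependent per-family p cutoff (0 if none rejected)
    q: float


def bh_fdr(p_values, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up over one explicit family of tests.

    Also returns the implied per-family threshold: the largest p-value that
    was rejected (the "p < ..." cutoff reported alongside corrected
    families), or 0.0 when nothing survives.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return FdrResult(np.zeros(0, dtype=bool), 0.0, q)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return FdrResult(reject, threshold, q)


@dataclass
class AnovaResult:
    f: float
    p: float
    r_squared: float
    table: pd.DataFrame
    group_means: pd.Series


def severity_anova(
    values, severity, study=None, order: list[str] | None = None
) -> AnovaResult:
    """ANOVA of a response on severity category with study as nuisance.

    Severity enters as an (ordered) categorical factor; the reported F and p
    are for the severity effect (type-II sums of squares), with the model
    R-squared alongside.
    """
    df = pd.DataFrame({"y": np.asarray(values, float), "sev": list(severity)})
    if df["sev"].nunique() < 2:
        raise ValueError("need at least 2 populated severity categories")
    if order is not None:
        df["sev"] = pd.Categorical(df["sev"], categories=order, ordered=True)
    formula = "y ~ C(sev)"
    if study is not None:
        df["study"] = list(study)
        if df["study"].nunique() > 1:
            formula += " + C(study)"
    model = smf.ols(formula, data=df).fit()
    try:
        table = sm.stats.anova_lm(model, typ=2)
    except Exception as exc:  # singular design
        raise ValueError(f"singular ANOVA design: {exc}") from exc
    row = table.loc["C(sev)"]
    return AnovaResult(
        f=float(row["F"]),
        p=float(row["PR(>F)"]),
        r_squared=float(model.rsquared),
        table=table,
        group_means=df.groupby("sev", observed=True)["y"].mean(),
    )
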