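"""Group-comparison statistics for the cohort table.

Implements the comparison battery used for the reference cohort:
Shapiro-Wilk normality and Levene variance checks, pooled-variance
(Student) two-sample t-tests in both raw-data and summary-statistic
forms, Pearson chi-square (no continuity correction) with Fisher's exact
fallback for sparse 2x2 tables, Pearson correlation, and age-stratified
subgroup analysis with a group x stratum interaction term from a linear
model. All p-values are two-sided.

The sign convention for group contrasts is (ASD - control), so a
positive t means the index is larger in the ASD group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.formula.api as smf

__all__ = [
    "GroupComparison",
    "two_sample_t",
    "two_sample_t_raw",
    "chi_square_2x2",
    "shapiro_wilk",
    "levene",
    "pearson_r",
    "subgroup_analysis",
    "compare_groups",
]


@dataclass
class GroupComparison:
    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    statistic: float
    df: float
    p: float
    test: str = "t"

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> GroupComparison:
    """Pooled-variance Student t from summary statistics.

    Group 1 is the control group, group 2 the ASD group; the statistic is
    signed (mean2 - mean1). df = n1 + n2 - 2. With zero variance in both
    groups, t is 0 for equal means and signed infinity otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean2 - mean1
    if sp2 == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * sstats.t.sf(abs(t), df)
    return GroupComparison(variable, mean1, sd1, n1, mean2, sd2, n2,
                           float(t), float(df), float(p))


def two_sample_t_raw(x1, x2, variable: str = "") -> GroupComparison:
    """Pooled-variance t from raw vectors; agrees exactly with the
    summary-statistic form computed from the same vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return two_sample_t(
        float(np.mean(x1)), float(np.std(x1, ddof=1)), x1.size,
        float(np.mean(x2)), float(np.std(x2, ddof=1)), x2.size,
        variable=variable,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   variable: str = "") -> GroupComparison:
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table.

    Rows are groups, columns are category counts: [[a, b], [c, d]].
    When any expected count is below 5, Fisher's exact test is used
    instead and the statistic is NaN (test name reports 'fisher').
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(rows, cols) / n
    if np.any(expected < 5):
        _, p = sstats.fisher_exact(table)
        stat, df, test = np.nan, np.nan, "fisher"
    else:
        stat, p, df, _ = sstats.chi2_contingency(table, correction=False)
        test = "chi2"
    return GroupComparison(variable, a, np.nan, int(rows[0]), c, np.nan,
                           int(rows[1]), float(stat), float(df), float(p), test=test)


def shapiro_wilk(sample):
    """Shapiro-Wilk normality test: returns (W, p). n must be in [3, 5000]."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    w, p = sstats.shapiro(x)
    return float(w), float(p)


def levene(sample1, sample2, center: str = "mean"):
    """Levene's homogeneity-of-variance test with an F reference.

    ``center='mean'`` is the classical form; ``'median'`` gives the
    Brown-Forsythe variant.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(x1) == 0 and np.ptp(x2) == 0:
        raise ValueError("constant inputs")
    stat, p = sstats.levene(x1, x2, center=center)
    return float(stat), float(p)


def pearson_r(x, y):
    """Pearson correlation with t-based two-sided p; returns (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def subgroup_analysis(
    cohort: pd.DataFrame,
    index_col: str,
    age_col: str = "age_yr",
    group_col: str = "group",
    age_cut: float = 8.0,
):
    """Age-stratified group comparisons plus a group x stratum interaction p.

    Strata are age < ``age_cut`` and age >= ``age_cut`` (the reference
    cohort's 4-7 vs 8-12 year split). Each stratum gets a pooled t-test;
    the interaction p comes from the Wald test of the product term in the
    linear model ``index ~ group * stratum``.
    """
    df = cohort[[index_col, age_col, group_col]].dropna().copy()
    df["stratum"] = np.where(df[age_col] < age_cut, "young", "old")
    results = {}
    for stratum, sub in df.groupby("stratum"):
        groups = sub[group_col].unique()
        if len(groups) < 2:
            raise ValueError(f"stratum {stratum!r} lacks both groups")
        ctrl = sub.loc[sub[group_col] == "control", index_col]
        asd = sub.loc[sub[group_col] == "ASD", index_col]
        results[stratum] = two_sample_t_raw(ctrl, asd, variable=index_col)
    model = smf.ols(
        f"Q('{index_col}') ~ C({group_col}) * C(stratum)", data=df
    ).fit()
    inter = [t for t in model.pvalues.index if ":" in t]
    interaction_p = float(model.pvalues[inter[0]])
    return results, interaction_p


def compare_groups(
    cohort: pd.DataFrame,
    variables,
    group_col: str = "group",
) -> pd.DataFrame:
    """Table of per-variable group comparisons (control vs ASD t-tests)."""
    rows = []
    ctrl = cohort[cohort[group_col] == "control"]
    asd = cohort[cohort[group_col] == "ASD"]
    for var in variables:
        c = ctrl[var].dropna()
        a = asd[var].dropna()
        res = two_sample_t_raw(c, a, variable=var)
        rows.append(
            {
                "variable": var,
                "control_mean": res.mean1,
                "control_sd": res.sd1,
                "asd_mean": res.mean2,
                "asd_sd": res.sd2,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
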