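"""Two-group comparison statistics with FDR correction and feature screening.

Each continuous feature is compared between groups with a pooled-variance
two-sample t test when both groups pass Shapiro-Wilk normality at
alpha = 0.05, and a Mann-Whitney U test otherwise (reported as a
tie-corrected normal-approximation Z; exact p for small tie-free
samples).  Categorical variables use a Pearson chi-square without
continuity correction.  Raw p-values across the feature family are
adjusted by Benjamini-Hochberg; the classifier feature screen uses
raw p < 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "shapiro_normality",
    "compare_groups",
    "chi_square_counts",
    "bh_fdr",
    "screen_features",
    "compare_cohort",
]

SHAPIRO_ALPHA = 0.05
#: largest per-group size at which the Mann-Whitney p is computed exactly
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of one two-group comparison.

    ``statistic`` is t for the t-branch and the normal-approximation Z
    for the Mann-Whitney branch, signed by the (first - second) group
    ordering.  ``p_fdr`` is filled in after family-wise adjustment.
    """

    feature: str
    test: str  # "t", "mannwhitney", or "chi2"
    statistic: float
    p_raw: float
    p_fdr: float | None = None


def shapiro_normality(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value; sample size must be 3..5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def _mw_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and the tie-corrected
    normal-approximation Z, without continuity correction."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 0.0
    return float(u1), float((u1 - mu) / np.sqrt(var))


def compare_groups(a, b, feature: str = "", force_test: str | None = None) -> GroupComparisonResult:
    """Compare two samples, picking the test from normality as described above.

    ``force_test`` overrides the Shapiro-Wilk gate with "t" or
    "mannwhitney".  A degenerate-variance t-branch falls back to
    Mann-Whitney with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")

    if force_test is None:
        use_t = False
        try:
            use_t = (
                shapiro_normality(a)[1] > SHAPIRO_ALPHA
                and shapiro_normality(b)[1] > SHAPIRO_ALPHA
            )
        except ValueError:
            use_t = False  # constant or too-small sample: rank test
    else:
        if force_test not in ("t", "mannwhitney"):
            raise ValueError("force_test must be 't' or 'mannwhitney'")
        use_t = force_test == "t"

    if use_t:
        pooled_var = (
            (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
        ) / (a.size + b.size - 2)
        if pooled_var == 0:
            if a.mean() == b.mean():
                return GroupComparisonResult(feature, "t", 0.0, 1.0)
            warnings.warn(f"{feature}: zero pooled variance, using Mann-Whitney")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            return GroupComparisonResult(feature, "t", float(t), float(p))

    u1, z = _mw_z(a, b)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N and not has_ties:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return GroupComparisonResult(feature, "mannwhitney", z, p)


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2 x k count table."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def screen_features(
    results: list[GroupComparisonResult], threshold: float = 0.10
) -> list[str]:
    """Feature names with raw p below the screening threshold, input order kept."""
    if not results:
        raise ValueError("no comparison results to screen")
    kept = [r.feature for r in results if r.p_raw < threshold]
    if not kept:
        warnings.warn(f"no features pass the p < {threshold} screen")
    return kept


def compare_cohort(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("ID", "NC"),
) -> list[GroupComparisonResult]:
    """Run compare_groups per feature and attach BH-FDR adjusted p-values."""
    a_mask = table[group_col] == groups[0]
    b_mask = table[group_col] == groups[1]
    results = [
        compare_groups(
            table.loc[a_mask, feat].to_numpy(),
            table.loc[b_mask, feat].to_numpy(),
            feature=feat,
        )
        for feat in features
    ]
    adjusted = bh_fdr([r.p_raw for r in results])
    return [replace(r, p_fdr=float(q)) for r, q in zip(results, adjusted)]
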