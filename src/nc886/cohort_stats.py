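"""Cohort-level statistics for categorical epigenotype data.

Prevalence estimation with Wilson score intervals, r x c categorical
association tests (Pearson chi-squared without continuity correction, with
an exact-test fallback for sparse 2x2 tables), the closed-form probability
of a small group being composed entirely of one epigenotype, and
expression-by-epigenotype fold changes.

The chi-squared convention is uncorrected: on the 2x2 table [[8,6],[12,2]]
(imprinted vs others, 14 cases vs 14 controls) it gives statistic 2.8 and
p = 0.094; with Yates correction the p value would be ~0.21 instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .epigenotyping import CATEGORIES, UNCLASSIFIED, CohortSummary, EpigenotypeCall

__all__ = [
    "AssociationResult",
    "PrevalenceEstimate",
    "prevalence_with_ci",
    "compare_groups",
    "all_one_category_probability",
    "expression_fold_change",
]


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a categorical association test on a contingency table."""

    table: tuple[tuple[int, ...], ...]
    test: str
    statistic: float | None
    p_value: float
    odds_ratio: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "table": [list(r) for r in self.table],
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "note": self.note,
        }


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A category proportion with its confidence interval."""

    category: str
    count: int
    total: int
    proportion: float
    ci_lower: float
    ci_upper: float
    conf_level: float

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "count": self.count,
            "total": self.total,
            "proportion": self.proportion,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "conf_level": self.conf_level,
        }


def prevalence_with_ci(
    summary: CohortSummary, category: str, conf_level: float = 0.95
) -> PrevalenceEstimate:
    """Estimate a category's prevalence with a Wilson score interval.

    The Wilson interval behaves sensibly at the small cohort sizes (n < 100)
    typical of population methylation surveys, unlike the Wald interval.
    """
    if summary.total <= 0:
        raise ValueError("cohort summary has zero total")
    if not (0.0 < conf_level < 1.0):
        raise ValueError("conf_level must be in (0, 1)")
    count = summary.counts.get(category, 0)
    lo, hi = proportion_confint(count, summary.total, alpha=1 - conf_level, method="wilson")
    return PrevalenceEstimate(
        category=category,
        count=count,
        total=summary.total,
        proportion=count / summary.total,
        ci_lower=float(lo),
        ci_upper=float(hi),
        conf_level=conf_level,
    )


def compare_groups(
    table: Sequence[Sequence[int]], exact_threshold: float = 3.0
) -> AssociationResult:
    """Test association in an r x c contingency table of epigenotype counts.

    Uses the Pearson chi-squared test without continuity correction.  For a
    2x2 table with any expected cell count below ``exact_threshold``, falls
    back to the two-sided exact (hypergeometric) test and flags the fallback
    in ``note``.  The default threshold of 3 keeps the uncorrected
    chi-squared convention on moderately sparse tables (the 8-vs-12
    imprinted split of a 28-sample cohort has minimum expected count 4 and
    is conventionally tested by chi-squared, p = 0.094) while near-empty
    cells trigger the exact test.  The odds ratio is reported for 2x2
    tables.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must have at least 2 rows and 2 columns")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)) or np.any(arr < 0):
            raise ValueError("table counts must be non-negative integers")
        arr = arr.astype(int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin; test undefined")

    tup = tuple(tuple(int(x) for x in row) for row in arr)
    odds_ratio = None
    if arr.shape == (2, 2):
        a, b = arr[0]
        c, d = arr[1]
        odds_ratio = float(a * d / (b * c)) if b * c > 0 else float("inf")

    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if arr.shape == (2, 2) and np.any(expected < exact_threshold):
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return AssociationResult(
            table=tup,
            test="fisher_exact",
            statistic=None,
            p_value=float(p),
            odds_ratio=odds_ratio,
            note=f"exact-test fallback: expected cell count < {exact_threshold}",
        )
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return AssociationResult(
        table=tup,
        test="chi_squared",
        statistic=float(chi2),
        p_value=float(p),
        odds_ratio=odds_ratio,
    )


def all_one_category_probability(prevalence: float, group_size: int) -> float:
    """Probability that a random group consists entirely of one category.

    Under independent sampling from a population where the category has the
    given prevalence, this is ``prevalence ** group_size``: e.g. with 75%
    imprinted individuals, a group of six is all-imprinted with probability
    0.75**6 = 0.178, i.e. 18%.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must be in [0, 1]")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    return float(prevalence**group_size)


def expression_fold_change(
    expr: Mapping[str, float] | pd.Series,
    calls: Iterable[EpigenotypeCall],
    group_a: str = "non_methylated",
    group_b: str = "imprinted",
) -> tuple[float, float]:
    """Fold change of mean RNA abundance between two epigenotype groups.

    Returns ``(mean(group_a) / mean(group_b), p)`` where p is the two-sided
    Wilcoxon rank-sum p value.  With both nc886 alleles permissive for
    expression, non-methylated individuals show a two-fold level relative to
    imprinted ones, and intermediates fall in between.
    """
    expr = pd.Series(expr, dtype=float)
    if (expr < 0).any():
        raise ValueError("expression values must be non-negative")
    groups: dict[str, list[float]] = {group_a: [], group_b: []}
    for call in calls:
        if call.category in groups and call.sample_id in expr.index:
            groups[call.category].append(float(expr[call.sample_id]))
    a, b = np.asarray(groups[group_a]), np.asarray(groups[group_b])
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"empty group after matching sample ids: "
            f"{group_a}={a.size}, {group_b}={b.size}"
        )
    if b.mean() == 0:
        raise ValueError(f"zero mean expression in denominator group {group_b!r}")
    fold = float(a.mean() / b.mean())
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return fold, 1.0  # identical constant groups: no evidence of difference
    p = float(stats.ranksums(a, b).pvalue)
    return fold, p
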