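"""Test-selection contract for group comparisons.

Proportion comparisons on 2x2 tables use Fisher's exact test for small
groups and the chi-squared test for large ones (total n > 40); distribution
comparisons use the two-sided Mann-Whitney U test with average-rank ties.
Chi-squared applies the Yates continuity correction by default for 2x2
tables (an uncorrected variant is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    test: str  # fisher_exact | chi_squared | mann_whitney_u
    statistic: float
    p: float
    n: int
    table: tuple | None = None
    continuity_correction: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def compare_proportions(table_2x2, n_threshold: int = 40, correction: bool = True) -> TestResult:
    """Two-sided test of association on a 2x2 count table.

    The chi-squared test is used when the table total exceeds ``n_threshold``
    and Fisher's exact test otherwise. ``correction`` toggles the Yates
    continuity correction on the chi-squared branch.
    """
    table = np.asarray(table_2x2, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    n = int(table.sum())
    if n > n_threshold:
        stat, p, _, _ = sps.chi2_contingency(table, correction=correction)
        return TestResult(
            test="chi_squared",
            statistic=float(stat),
            p=float(p),
            n=n,
            table=tuple(map(tuple, table)),
            continuity_correction=correction,
        )
    stat, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(
        test="fisher_exact",
        statistic=float(stat),
        p=float(p),
        n=n,
        table=tuple(map(tuple, table)),
    )


def compare_distributions(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (average-rank tie handling)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=len(x) + len(y),
    )


def significance_stars(p: float) -> str:
    """Conventional significance bands: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
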