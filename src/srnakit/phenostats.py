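"""Statistics for penetrance and seam-cell phenotype comparisons.

Two procedures: a Pearson chi-square test (no continuity correction) on
genotype x phenotype-category contingency tables of animal counts, and
a two-tailed two-sample t-test on per-animal seam cell counts (Welch by
default, pooled-variance optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    warning: str | None = None

    @property
    def stars(self) -> str:
        if self.pvalue < 0.001:
            return "***"
        if self.pvalue < 0.01:
            return "**"
        if self.pvalue < 0.05:
            return "*"
        return "N.S."


def chisq_test(table) -> TestResult:
    """Pearson chi-square on a contingency table of raw animal counts.

    Cells must be non-negative integers (scaled tables are refused);
    df = (rows-1)(cols-1); a warning flag is set when any expected
    count is below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.rint(obs)):
        raise ValueError("cells must be non-negative integer counts")
    row_totals = obs.sum(axis=1)
    col_totals = obs.sum(axis=0)
    if (row_totals == 0).any():
        raise ValueError("every row total must be > 0")
    if (col_totals == 0).any():
        raise ValueError("degenerate table: a phenotype category has zero total")
    expected = np.outer(row_totals, col_totals) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    pvalue = float(stats.chi2.sf(statistic, df))
    warning = "expected count < 5" if (expected < 5).any() else None
    return TestResult(statistic, df, pvalue, warning)


def t_test(a, b, pooled: bool = False) -> TestResult:
    """Two-sided two-sample t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, len(a) + len(b) - 2, 1.0)
        return TestResult(math.inf if a.mean() > b.mean() else -math.inf,
                          len(a) + len(b) - 2, 0.0, warning="zero variance")
    if pooled:
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue))
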