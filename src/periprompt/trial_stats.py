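"""Small-sample trial statistics over fixed tables and summary statistics.

Covers the three statistical primitives a pilot feasibility trial reports:
proportions rounded to printed precision, the Pearson chi-square on a 2x2
contingency table (no continuity correction by default), and two-sample t
tests computed from group summary statistics (pooled-variance Student t by
default, Welch optional). The heavy lifting is delegated to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stream_model import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "proportion_pct",
    "pearson_chi2",
    "two_sample_t_from_summary",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed percentages).

    Python's built-in ``round`` is banker's rounding; clinically reported
    percentages round 0.5 up.
    """
    scale = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts; rows are arms, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be >= 0")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("grand total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, and standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("group size must be >= 2")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


def proportion_pct(numerator: int, denominator: int) -> tuple[float, int]:
    """Fraction and integer percentage (half away from zero) of a count pair."""
    if denominator < 1:
        raise ValidationError("denominator must be >= 1")
    if not (0 <= numerator <= denominator):
        raise ValidationError("need 0 <= numerator <= denominator")
    frac = numerator / denominator
    return frac, int(round_half_away(100.0 * frac))


def pearson_chi2(
    table: ContingencyTable2x2, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square statistic, df, and two-sided p for a 2x2 table.

    No continuity correction by default; set ``correction=True`` for Yates.
    A zero row or column margin leaves the statistic undefined.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_sample_t_from_summary(
    g1: GroupSummary, g2: GroupSummary, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t test from summary statistics.

    Pooled-variance Student t (df = n1 + n2 - 2) when ``pooled``, Welch
    otherwise. Two degenerate cases: both SDs zero with equal means gives
    t = 0, p = 1; both SDs zero with unequal means is undefined.
    """
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            df = g1.n + g2.n - 2 if pooled else float(g1.n + g2.n - 2)
            return 0.0, float(df), 1.0
        raise ValidationError("t undefined: zero variance in both groups, unequal means")
    t, p = stats.ttest_ind_from_stats(
        mean1=g1.mean,
        std1=g1.sd,
        nobs1=g1.n,
        mean2=g2.mean,
        std2=g2.sd,
        nobs2=g2.n,
        equal_var=pooled,
    )
    if pooled:
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(t), df, float(p)
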