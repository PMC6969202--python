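"""Univariate group statistics: pooled t, chi-square, Pearson r, Fisher Z, F.

These are the demographic and post-hoc tests that accompany the multivariate
analyses: pooled-variance two-sample t-tests (computable from raw vectors or
from printed n/mean/SD summaries), Pearson chi-square for count tables,
Pearson correlations with t-based p-values, Fisher r-to-z comparison of two
independent correlations, and the variance-ratio F-test.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SummaryGroup:
    """Summary statistics of one group: n, mean, SD (sample convention)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def from_raw(cls, x) -> "SummaryGroup":
        x = np.asarray(x, dtype=float).ravel()
        return cls(n=x.size, mean=float(x.mean()), sd=float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its degrees of freedom and two-sided p-value."""

    statistic: float
    df: float | tuple[float, float]
    p: float


def pooled_t(g1: SummaryGroup, g2: SummaryGroup) -> StatResult:
    """Pooled-variance two-sample t-test from group summaries.

    t = (m1 - m2) / sqrt(s_p^2 (1/n1 + 1/n2)) with the pooled variance
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2) and
    df = n1 + n2 - 2.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("both group SDs are zero; t is undefined")
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult(statistic=float(t), df=df, p=float(p))


def pooled_t_raw(x1, x2) -> StatResult:
    """Pooled two-sample t from raw vectors; identical to the summary route."""
    return pooled_t(SummaryGroup.from_raw(x1), SummaryGroup.from_raw(x2))


def chi_square(table) -> StatResult:
    """Pearson chi-square test of independence, no continuity correction.

    df = (rows - 1)(cols - 1).  Raises on negative counts or a zero marginal.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column marginal")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return StatResult(statistic=float(stat), df=int(df), p=float(p))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> StatResult:
    """Compare two independent Pearson correlations via Fisher's r-to-z.

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), standard-normal
    two-sided p.  Antisymmetric in its two correlations.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("each sample needs n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return StatResult(statistic=float(z), df=float("inf"), p=float(p))


def pearson_r(x, y) -> StatResult:
    """Pearson correlation with a t-distributed two-sided p on n - 2 df."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input")
    res = stats.pearsonr(x, y)
    return StatResult(statistic=float(res.statistic), df=x.size - 2,
                      p=float(res.pvalue))


def variance_ratio(g1: SummaryGroup, g2: SummaryGroup) -> StatResult:
    """Variance-ratio F-test: F = s1^2 / s2^2 on (n1 - 1, n2 - 1) df.

    The two-sided p doubles the smaller tail probability.
    """
    if g2.sd == 0:
        raise ValueError("second group SD is zero; F is undefined")
    f = g1.sd**2 / g2.sd**2
    df = (g1.n - 1, g2.n - 1)
    cdf = stats.f.cdf(f, *df)
    p = 2 * min(cdf, 1 - cdf)
    return StatResult(statistic=float(f), df=df, p=float(min(p, 1.0)))
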