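"""Shared statistical primitives.

Thin, strict wrappers around the classical tests every pipeline stage
uses: chi-squared survival function and independence test (Pearson
statistic, no continuity correction), Kruskal-Wallis with tie
correction, Benjamini-Hochberg / Bonferroni adjustment, Pearson
correlation with a t-distribution p-value, and a two-sided Fisher exact
test computed by hypergeometric enumeration.

Conventions, fixed package-wide:

* the chi-squared independence test drops all-zero rows and columns and
  refuses tables with fewer than two informative rows or columns;
* Kruskal-Wallis uses the chi-squared approximation with k-1 degrees of
  freedom at any sample size, returning H=0, p=1 when every observation
  is tied;
* the Pearson p-value is the two-sided t approximation with n-2 df;
* the two-sided Fisher p sums hypergeometric point probabilities no
  larger than the observed one (relative tie tolerance 1e-9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DegenerateTableError",
    "chi2_sf",
    "chi2_independence",
    "kruskal_wallis",
    "adjust_pvalues",
    "pearson_with_p",
    "fisher_exact_two_sided",
]


class DegenerateTableError(ValueError):
    """Contingency table with < 2 informative rows or columns."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: int | None = None


def chi2_sf(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if statistic < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.sf(statistic, df))


def chi2_independence(table) -> TestResult:
    """Pearson chi-squared test of independence on an R x C count table.

    All-zero rows/columns are dropped before testing; no Yates
    correction is applied.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError(
            f"table has {t.shape[0]} informative rows and {t.shape[1]} columns"
        )
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(stat), p=float(p), df=int(df))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        # complete ties: H is defined as 0 and carries no evidence
        return TestResult(statistic=0.0, p=1.0, df=df)
    stat, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(stat), p=float(p), df=df)


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, returned in the input order.

    ``bh``: step-up q_i = min_{j >= i} (m * p_(j) / j), capped at 1.
    ``bonferroni``: min(1, m * p).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-dimensional")
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        q = np.empty(m)
        q[order] = q_sorted
        return q
    raise ValueError(f"unknown method {method!r}")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, min(1.0, p)


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table -> (odds ratio, p).

    The p-value is the sum, over the hypergeometric support, of point
    probabilities not exceeding the observed one (relative tie
    tolerance 1e-9).  The odds ratio is the unconditional a*d / (b*c),
    with inf when b*c = 0 and a*d > 0, and nan for 0/0.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return odds, 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return odds, min(1.0, p)
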