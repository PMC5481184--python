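"""Exact small-sample nonparametric tests and summary statistics.

Left-versus-right comparisons in this domain involve a handful of embryos per
group, so asymptotic p-values are unreliable.  This module computes the exact
permutation null distributions of the Mann-Whitney U statistic (all
``C(n1+n2, n1)`` group assignments) and of the Wilcoxon signed-rank statistic
(all ``2**n`` sign assignments) by dynamic programming, which enumerates the
same distributions as brute force without materialising every arrangement.
For larger samples, or in the presence of ties for the rank-sum test, the
tie-corrected normal approximation with continuity correction is used and the
``method`` field of the result records the switch.

Conventions
-----------
* Exact two-sided p-values use the doubling rule ``min(1, 2 * min(tail p))``.
* Zero differences in the signed-rank test are dropped before ranking
  (Wilcoxon's original convention); ``zero_method="pratt"`` ranks them first
  and then discards them.
* ``alternative="greater"`` means the first sample (x, or the x-member of each
  pair) tends to be larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import AllZeroDifferences, EmptySample, ZeroDenominator

__all__ = [
    "TestResult",
    "RatioSummary",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "mean_sem",
    "lr_ratio_summary",
]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    alternative: str
    n1: int
    n2: Optional[int] = None  # None for paired tests; n1 is then #pairs used


@dataclass(frozen=True)
class RatioSummary:
    """Per-embryo right/left ratios summarised as mean +/- SEM."""

    ratios: tuple
    mean: float
    sem: Optional[float]  # None when n == 1 (SEM undefined)
    n: int
    test: Optional[TestResult] = None


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


# ---------------------------------------------------------------------------
# Mann-Whitney U (Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Count of rank subsets per U value under the exact null (no ties).

    ``counts[u]`` is the number of the ``C(n1+n2, n1)`` equally likely
    assignments of ranks ``1..n1+n2`` to group 1 whose U statistic equals
    ``u``; equivalent to full enumeration.
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    # dp[k, s]: number of k-subsets of ranks processed so far with rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            dp[k, rank:] += dp[k - 1, : max_sum + 1 - rank]
    rank_sums = dp[n1]
    offset = n1 * (n1 + 1) // 2  # U = R1 - n1(n1+1)/2
    return rank_sums[offset : offset + n1 * n2 + 1].copy()


def _exact_u_pvalues(u: float, n1: int, n2: int) -> tuple[float, float]:
    """(P(U >= u), P(U <= u)) under the exact no-tie null."""
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    ui = int(round(u))
    p_ge = counts[ui:].sum() / total
    p_le = counts[: ui + 1].sum() / total
    return p_ge, p_le


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 20,
) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact p-value by enumeration of all group assignments when
    ``n1 + n2 <= exact_max_n`` and the pooled data contain no ties; otherwise
    midranks with tie-corrected, continuity-corrected normal approximation.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise EmptySample("both samples must contain at least one value")
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 + n2 <= exact_max_n and not has_ties:
        p_ge, p_le = _exact_u_pvalues(u1, n1, n2)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u1, float(p), "exact", alternative, n1, n2)

    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = math.sqrt(max(sigma2, 0.0))
    if sigma == 0.0:
        p_ge = p_le = 1.0
    else:
        p_ge = _sps.norm.sf((u1 - mu - 0.5) / sigma)
        p_le = _sps.norm.cdf((u1 - mu + 0.5) / sigma)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(u1, float(p), "normal_approx", alternative, n1, n2)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

def _wplus_null_counts(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Distribution of 2*W+ over all 2**n equally likely sign assignments.

    Midranks are multiples of 0.5, so they are doubled to integers first; the
    subset-sum dynamic program is then an exact enumeration of sign vectors.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] += counts[:-r] if r > 0 else counts[:]
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
    exact_max_n: int = 20,
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples.

    ``x`` may be the paired differences directly (``y=None``) or the first
    members of the pairs with ``y`` the second.  Exact p-value by enumeration
    of all ``2**n`` sign assignments (via the equivalent subset-sum dynamic
    program, which also handles midranks of tied |differences|) for
    ``n <= exact_max_n``; normal approximation beyond.
    """
    _check_alternative(alternative)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.size == 0:
        raise EmptySample("no pairs supplied")
    nonzero = d != 0
    if not nonzero.any():
        raise AllZeroDifferences("all paired differences are zero")

    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = _sps.rankdata(np.abs(d_used))
    else:  # pratt: rank with zeros, then drop their ranks
        ranks_all = _sps.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n = len(d_used)
    w_plus = ranks[d_used > 0].sum()

    if n <= exact_max_n:
        doubled = [int(round(2 * r)) for r in ranks]
        counts = _wplus_null_counts(doubled)
        total = counts.sum()
        wi = int(round(2 * w_plus))
        p_ge = counts[wi:].sum() / total
        p_le = counts[: wi + 1].sum() / total
        method = "exact"
    else:
        mu = ranks.sum() / 2.0
        sigma = math.sqrt((ranks**2).sum() / 4.0)
        p_ge = _sps.norm.sf((w_plus - mu - 0.5) / sigma)
        p_le = _sps.norm.cdf((w_plus - mu + 0.5) / sigma)
        method = "normal_approx"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(float(w_plus), float(p), method, alternative, n, None)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def mean_sem(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Mean and standard error of the mean (sd with n-1 denominator / sqrt(n)).

    With a single value the SEM is undefined and returned as ``None``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptySample("mean_sem of an empty sequence")
    if v.size == 1:
        return float(v[0]), None
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def lr_ratio_summary(
    pairs: Sequence[tuple[float, float]],
    method: str = "per_pair",
    test: bool = False,
) -> RatioSummary:
    """Summarise paired (left, right) measurements as right/left ratios.

    ``method="per_pair"`` (default) averages the per-embryo R/L ratios;
    ``method="ratio_of_means"`` reports mean(right)/mean(left) instead (its
    SEM is then None).  With ``test=True`` an exact two-sided signed-rank
    test of left versus right is attached.
    """
    if method not in ("per_pair", "ratio_of_means"):
        raise ValueError("method must be 'per_pair' or 'ratio_of_means'")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise EmptySample("pairs must be a non-empty sequence of (left, right)")
    left, right = arr[:, 0], arr[:, 1]
    if np.any(left <= 0):
        raise ZeroDenominator("left values must be positive to form R/L ratios")
    ratios = right / left
    if method == "per_pair":
        mean, sem = mean_sem(ratios)
    else:
        mean, sem = float(right.mean() / left.mean()), None
    result = None
    if test:
        result = wilcoxon_signed_rank(right, left, alternative="two-sided")
    return RatioSummary(tuple(float(r) for r in ratios), mean, sem, len(ratios), result)
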