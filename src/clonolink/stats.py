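"""Small-sample tests shared across the repertoire and transcriptome analyses.

Fisher's exact test is implemented with exact integer arithmetic: for a 2x2
table with fixed margins the conditional distribution of the top-left cell is
hypergeometric, and the standard two-sided p-value is the total probability of
all margin-fixed tables whose probability does not exceed that of the observed
table.  Working with the integer weights C(r1, x) * C(r2, c1 - x) (which are
proportional to the hypergeometric pmf) makes the "not more probable than
observed" comparison exact, so ties are never mis-resolved by floating-point
rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_exact",
    "fisher_exact_p",
    "odds_ratio",
    "rank_sum_test",
    "FisherResult",
    "RankSumResult",
]


@dataclass(frozen=True)
class FisherResult:
    table: np.ndarray
    odds_ratio: float
    p: float


@dataclass(frozen=True)
class RankSumResult:
    u: float
    p: float
    method: str


def _check_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("contingency table entries must be non-negative")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("contingency table entries must be integers")
    return arr.astype(np.int64)


def fisher_exact_p(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table.

    Sums the probabilities of every table with the same margins whose
    probability is less than or equal to that of the observed table.
    Degenerate margins (an empty row or column) give p = 1.
    """
    arr = _check_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or (n - c1) == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    total = math.comb(n, c1)
    p = sum(w for w in weights if w <= observed) / total
    return min(1.0, p)


def odds_ratio(table, haldane: bool = True) -> float:
    """Sample odds ratio (ad/bc); Haldane 0.5 correction when any cell is 0."""
    arr = _check_table(table).astype(float)
    if haldane and np.any(arr == 0):
        arr = arr + 0.5
    a, b = arr[0]
    c, d = arr[1]
    return (a * d) / (b * c)


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test with odds ratio."""
    arr = _check_table(table)
    return FisherResult(table=arr, odds_ratio=odds_ratio(arr), p=fisher_exact_p(arr))


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Uses the exact null distribution when both samples have at most 8
    observations and the pooled values are tie-free; otherwise the normal
    approximation with tie correction.  When every pooled value is identical
    the statistic carries no information and p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return RankSumResult(u=x.size * y.size / 2.0, p=1.0, method="degenerate")
    tie_free = np.unique(pooled).size == pooled.size
    if x.size <= 8 and y.size <= 8 and tie_free:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0
    return RankSumResult(u=float(res.statistic), p=min(1.0, p), method=method)
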