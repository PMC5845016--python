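"""Rank-based two-sample tests and rank correlation.

Small samples (pooled n <= 12 for the rank-sum family, n <= 9 for the
Spearman permutation test) are handled by exact enumeration; larger
samples use the standard normal / Student-t approximations with mid-rank
tie correction and optional +-0.5 continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb, sqrt

import numpy as np
from scipy import stats

__all__ = ["TestResult", "wilcoxon_rank_sum", "siegel_tukey", "spearman"]

EXACT_MAX_POOLED = 12
EXACT_MAX_SPEARMAN = 9


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (mid-ranks under ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    wx = ranks[: len(x)].sum()
    return wx - len(x) * (len(x) + 1) / 2.0


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Enumerate all C(N, nx) group assignments of the pooled values.

    Permuting the observed values (rather than 1..N ranks) makes the
    enumeration exact under ties as well.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    u_obs = _u_statistic(x, y)
    n_total = comb(len(pooled), nx)
    offset = nx * (nx + 1) / 2.0
    n_le = n_ge = 0
    for idx in combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    p_less = n_le / n_total
    p_greater = n_ge / n_total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def wilcoxon_rank_sum(
    x,
    y,
    continuity: bool = True,
    alternative: str = "two-sided",
    exact: bool | None = None,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    ``exact=None`` auto-selects exact enumeration when the pooled sample
    size is at most 12.  The large-sample path uses the tie-corrected
    normal approximation with a +-0.5 continuity correction when
    ``continuity`` is set.  ``alternative`` refers to the location of x
    relative to y ('less' means x shifted downward).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    u = _u_statistic(x, y)
    if exact is None:
        exact = n <= EXACT_MAX_POOLED
    if exact:
        p = _exact_rank_sum_p(x, y, alternative)
        return TestResult(statistic=u, p_value=p, method="wilcoxon")

    mu = nx * ny / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(statistic=u, p_value=1.0, method="wilcoxon")
    sigma = sqrt(sigma2)
    cc = 0.5 if continuity else 0.0

    def z_of(dev_sign: int) -> float:
        # dev_sign +1 for upper tail, -1 for lower
        return (u - mu - dev_sign * cc) / sigma

    if alternative == "greater":
        p = stats.norm.sf(z_of(+1))
    elif alternative == "less":
        p = stats.norm.cdf(z_of(-1))
    else:
        p = 2.0 * min(stats.norm.sf(z_of(+1)), stats.norm.cdf(z_of(-1)))
        p = min(1.0, p)
    return TestResult(statistic=u, p_value=max(p, np.finfo(float).tiny), method="wilcoxon")


def siegel_tukey_ranks(n: int) -> np.ndarray:
    """Alternating extreme ranks for n sorted values.

    Rank 1 goes to the smallest value, ranks 2-3 to the two largest,
    ranks 4-5 to the next two smallest, and so on, converging on the
    middle.  Returns the rank assigned to each sorted position.
    """
    ranks = np.empty(n, dtype=float)
    lo, hi = 0, n - 1
    rank = 1
    take_low, burst = True, 1  # first burst is a single low value
    while lo <= hi:
        for _ in range(burst):
            if lo > hi:
                break
            if take_low:
                ranks[lo] = rank
                lo += 1
            else:
                ranks[hi] = rank
                hi -= 1
            rank += 1
        take_low = not take_low
        burst = 2
    return ranks


def siegel_tukey(x, y, alternative: str = "two-sided", exact: bool | None = None) -> TestResult:
    """Siegel-Tukey test for differences in spread.

    Pooled values get alternating extreme ranks (small ranks at the
    extremes when counting from rank 1 at the minimum), tied values get
    mid-ranks, and a Wilcoxon rank-sum is run on the resulting scores.
    When the pooled count is odd the single middle observation is
    dropped (classical convention), keeping the rank sum balanced.
    A sample with larger spread collects the early (extreme) ranks, so
    its rank-score sum is *smaller*: 'greater' means x more spread.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    labels = np.concatenate([np.zeros(len(x), dtype=int), np.ones(len(y), dtype=int)])
    order = np.argsort(pooled, kind="mergesort")
    n = len(pooled)
    keep = np.ones(n, dtype=bool)
    if n % 2 == 1:
        keep[order[n // 2]] = False
    pooled, labels = pooled[keep], labels[keep]
    order = np.argsort(pooled, kind="mergesort")
    st = siegel_tukey_ranks(len(pooled))
    scores = np.empty(len(pooled))
    scores[order] = st
    # mid-ranks for ties in the underlying values
    for v in np.unique(pooled):
        mask = pooled == v
        if mask.sum() > 1:
            scores[mask] = scores[mask].mean()
    sx, sy = scores[labels == 0], scores[labels == 1]
    # larger spread -> extreme positions -> smaller Siegel-Tukey scores
    flipped = {"two-sided": "two-sided", "greater": "less", "less": "greater"}[alternative]
    res = wilcoxon_rank_sum(sx, sy, continuity=False, alternative=flipped, exact=exact)
    return TestResult(statistic=res.statistic, p_value=res.p_value, method="siegel_tukey")


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact: bool | None = None) -> TestResult:
    """Spearman rank correlation with two-sided p-value.

    Mid-ranks under ties; p from the t-approximation
    t = rho * sqrt((n-2) / (1 - rho^2)), or from full enumeration of the
    n! rank permutations when n <= 9.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if np.isnan(rho):
        return TestResult(statistic=np.nan, p_value=np.nan, method="spearman")
    if exact is None:
        exact = n <= EXACT_MAX_SPEARMAN
    if exact:
        count = total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = np.finfo(float).tiny
        else:
            t = rho * sqrt((n - 2) / (1.0 - rho**2))
            p = min(1.0, 2.0 * stats.t.sf(abs(t), n - 2))
    return TestResult(statistic=rho, p_value=max(p, np.finfo(float).tiny), method="spearman")
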