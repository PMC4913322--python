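"""Rank statistics with exact small-sample null distributions.

Implements the tests the scoring layer depends on: paired Wilcoxon
signed-rank, unpaired Wilcoxon rank-sum, Benjamini-Hochberg adjustment,
Spearman correlation and linear-interpolation quantiles.

Exactness policy: the signed-rank null distribution is computed exactly by
convolution for up to ``SIGNED_RANK_EXACT_MAX`` non-zero pairs (ties are
handled through doubled mid-ranks, which are always integers); the rank-sum
distribution is exact for pooled sizes up to ``RANK_SUM_EXACT_MAX``.  Beyond
those sizes a tie-corrected normal approximation with continuity correction
is used.  Spearman p-values are exact by full permutation for n <= 8 and
use the t approximation above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as _sps

SIGNED_RANK_EXACT_MAX = 25
RANK_SUM_EXACT_MAX = 12
SPEARMAN_EXACT_MAX = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided location test.

    ``direction`` is the sign of the estimated location shift (+1, -1 or 0
    when the test is degenerate or the shift is exactly zero).
    """

    statistic: float
    p_two_sided: float
    n_effective: int
    direction: int


def _sign(x: float) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def _finite_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _signed_rank_counts(doubled: np.ndarray) -> np.ndarray:
    """Count, for every achievable doubled rank sum w, the number of sign
    assignments whose positive-part sum equals w."""
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        r = int(r)
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def _two_sided_from_counts(counts: np.ndarray, obs: int) -> float:
    total = counts.sum()
    lower = counts[: obs + 1].sum() / total
    upper = counts[obs:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    ``y`` may be omitted to test differences ``x`` against zero.  Zero
    differences are dropped before ranking.  If all differences are zero
    (or no complete pair exists) the test is degenerate: p = 1,
    direction 0.
    """
    if y is None:
        d = np.asarray(x, dtype=float)
        d = d[np.isfinite(d)]
    else:
        xv, yv = _finite_pairs(x, y)
        d = xv - yv
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, 0)
    ranks = _sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    direction = _sign(float(d.mean()))
    if n <= SIGNED_RANK_EXACT_MAX:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(doubled)
        obs = int(round(2 * w_pos))
        p = _two_sided_from_counts(counts, obs)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return TestResult(w_pos, 1.0, n, direction)
        z = (w_pos - mu - 0.5 * _sign(w_pos - mu)) / math.sqrt(var)
        p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return TestResult(w_pos, float(p), n, direction)


def _rank_sum_counts(doubled: np.ndarray, nx: int) -> np.ndarray:
    """Distribution of the doubled rank sum of a size-``nx`` subset drawn
    without replacement from the pooled doubled mid-ranks."""
    total = int(doubled.sum())
    dp = np.zeros((nx + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled:
        r = int(r)
        for k in range(min(nx, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[nx]


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("rank-sum test requires both groups non-empty")
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    w_x = float(ranks[:nx].sum())
    n = nx + ny
    direction = _sign(float(x.mean() - y.mean()))
    if n <= RANK_SUM_EXACT_MAX:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _rank_sum_counts(doubled, nx)
        obs = int(round(2 * w_x))
        p = _two_sided_from_counts(counts, obs)
    else:
        mu = nx * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / float(n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(w_x, 1.0, n, direction)
        z = (w_x - mu - 0.5 * _sign(w_x - mu)) / math.sqrt(var)
        p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return TestResult(w_x, float(p), n, direction)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at
    1, returned in the input order.  Missing entries (NaN) pass through
    and do not count towards m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        bad = pv[(pv < 0) | (pv > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[mask] = qv
    return out


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    degenerate: bool = False


def _perm_pool(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=int)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with exact permutation p for n <= 8.

    Pairwise-complete; requires n >= 3.  A constant vector makes rho
    undefined: the result is flagged ``degenerate`` (treated downstream
    as no significant correlation).
    """
    xv, yv = _finite_pairs(x, y)
    n = xv.size
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, degenerate=True)
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return CorrelationResult(float("nan"), float("nan"), n, degenerate=True)
    rx = _sps.rankdata(xv)
    ry = _sps.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX:
        perms = _perm_pool(n)
        ry_perms = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perms - ry_perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        rho_all = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = min(1.0, 2.0 * _sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, float(p), n)


def quantile(values, q: float) -> float:
    """Linear-interpolation quantile (position 1 + q*(n-1) on the sorted
    non-missing values)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("quantile of an empty vector")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile fraction outside [0, 1]: {q}")
    return float(np.quantile(v, q, method="linear"))


def pearson(x, y) -> tuple[float, int]:
    """Pearson correlation over pairwise-complete entries; returns (r, n)."""
    xv, yv = _finite_pairs(x, y)
    n = xv.size
    if n < 3:
        raise ValueError("Pearson correlation requires >= 3 complete pairs")
    return float(np.corrcoef(xv, yv)[0, 1]), n
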