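"""Rank and ECDF statistics used by the pausing comparisons.

Implemented here rather than called from a stats library so the numerical
route is explicit and independently checkable: the Mann-Whitney U uses the
normal approximation with tie correction and continuity correction (exact
enumeration when both samples are small and untied), and the two-sample
Kolmogorov-Smirnov uses the ECDF sup-distance with the asymptotic
one-sample-equivalent null distribution.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import stats as _sps
from scipy.stats import distributions as _dist

__all__ = ["mann_whitney_u", "ks_two_sample", "ecdf", "binom_upper_tail"]


def mann_whitney_u(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U of the first sample, two-sided p).  Exact null enumeration is
    used when both samples have at most ``exact_max_n`` observations and there
    are no ties; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _sps.rankdata(combined)
    u1 = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and nx <= exact_max_n and ny <= exact_max_n:
        p = _mwu_exact_p(nx, ny, u1)
    else:
        n = nx + ny
        mu = nx * ny / 2
        tie_term = float(((tie_counts**3) - tie_counts).sum())
        sigma = math.sqrt(nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1))))
        if sigma == 0:
            return u1, 1.0
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sigma
        p = 2 * _sps.norm.sf(abs(z))
    return u1, float(min(p, 1.0))


@lru_cache(maxsize=None)
def _mwu_counts(nx: int, ny: int) -> np.ndarray:
    """Null distribution of U over 0..nx*ny.

    Classic recurrence f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u): the
    largest x either ranks above all n y's (contributing n to U) or the
    largest observation is a y.
    """
    size = nx * ny + 1
    # g[m] holds f(m, n, .) for the current n
    g = [np.zeros(size) for _ in range(nx + 1)]
    for m in range(nx + 1):
        g[m][0] = 1.0  # n = 0: U is always 0
    for n in range(1, ny + 1):
        new = [np.zeros(size) for _ in range(nx + 1)]
        new[0][0] = 1.0
        for m in range(1, nx + 1):
            arr = g[m].copy()
            arr[n:] += new[m - 1][: size - n]
            new[m] = arr
        g = new
    return g[nx]


def _mwu_exact_p(nx: int, ny: int, u1: float) -> float:
    counts = _mwu_counts(nx, ny)
    total = counts.sum()
    u_lo = min(u1, nx * ny - u1)
    p = 2 * counts[: int(u_lo) + 1].sum() / total
    return min(1.0, p)


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Sorted support and cumulative fractions of an empirical CDF."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    return v, np.arange(1, v.size + 1) / v.size


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p).

    Statistic is the sup distance between the two ECDFs; the p-value uses the
    one-sample KS null at the effective sample size n*m/(n+m).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("finite values only (cap infinite pausing indices first)")
    sa, sb = np.sort(a), np.sort(b)
    grid = np.concatenate([sa, sb])
    cdf_a = np.searchsorted(sa, grid, side="right") / sa.size
    cdf_b = np.searchsorted(sb, grid, side="right") / sb.size
    d = float(np.abs(cdf_a - cdf_b).max())
    m, n = sorted([float(a.size), float(b.size)], reverse=True)
    en = m * n / (m + n)
    p = float(np.clip(_dist.kstwo.sf(d, int(round(en))), 0.0, 1.0))
    return d, p


def binom_upper_tail(k: int, n: int, rate: float) -> float:
    """P(X >= k) for X ~ Binomial(n, rate); the motif enrichment p-value."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(_sps.binom.sf(k - 1, n, rate))
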