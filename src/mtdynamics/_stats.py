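"""Small statistical helpers shared across modules.

Medians are summarized with order-statistic (binomial) confidence
intervals, means with t-based intervals.  Both are the standard
nonparametric/parametric choices for pooled event-level measurements.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["ols_line", "median_ci", "mean_ci", "r_squared"]


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least-squares line fit.

    Returns ``(slope, intercept, r_squared)``.  ``r_squared`` is 0 when the
    response is constant (degenerate SStot).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a line fit")
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("x values are degenerate")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    sst = float(np.sum((y - ym) ** 2))
    if sst == 0.0:
        return slope, intercept, 0.0
    sse = float(np.sum((y - (intercept + slope * x)) ** 2))
    return slope, intercept, 1.0 - sse / sst


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    return ols_line(x, y)[2]


def median_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Median with a conservative order-statistic (binomial) CI.

    The interval is ``(x_(k), x_(n+1-k))`` with ``k`` the largest order such
    that the two-sided coverage is at least ``level``.  For very small n the
    interval degenerates to the sample range.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("median of empty sample")
    med = float(np.median(v))
    if n == 1:
        return med, med, med
    alpha = (1.0 - level) / 2.0
    # largest k with P(Binom(n, 1/2) < k) <= alpha
    k = int(stats.binom.ppf(alpha, n, 0.5))
    while k > 0 and stats.binom.cdf(k - 1, n, 0.5) > alpha:
        k -= 1
    k = max(k, 0)
    lo = v[max(k - 1, 0)] if k >= 1 else v[0]
    hi = v[min(n - k, n - 1)] if k >= 1 else v[-1]
    return med, float(lo), float(hi)


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a t-based two-sided CI."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        raise ValueError("mean of empty sample")
    m = float(v.mean())
    if n == 1:
        return m, m, m
    sem = float(v.std(ddof=1)) / np.sqrt(n)
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1)) * sem
    return m, m - half, m + half
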