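"""Culture growth and scoring statistics: doubling times from OD600 curves
and binomial proportions with their standard errors.

Doubling time comes from the maximal log-linear window: the longest
contiguous span of samples (within an OD gate) whose log2(OD) vs time
regression keeps R² above a threshold; the doubling time is 1/slope of
that fit.  Wells that never sustain log-linear growth are flagged rather
than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._stats import ols_line
from .simulate import GrowthCurve

__all__ = [
    "DoublingFit",
    "ProportionResult",
    "fit_doubling_time",
    "normalize_doubling",
    "proportion_with_se",
]


@dataclass
class DoublingFit:
    doubling_time_min: Optional[float]
    window_min: Optional[tuple[float, float]]
    r_squared: Optional[float]
    n_points: int
    no_growth: bool
    reason: str = ""


def fit_doubling_time(
    curve: GrowthCurve,
    min_r2: float = 0.99,
    od_lo: float = 0.02,
    od_hi: float = 1.0,
    min_points: int = 10,
    blank: float = 0.0,
) -> DoublingFit:
    """Doubling time from the maximal log-linear window of an OD600 curve.

    Among contiguous windows of at least ``min_points`` samples whose OD
    (after optional ``blank`` subtraction) lies in [``od_lo``, ``od_hi``],
    the longest one with log2(OD)-vs-time R² >= ``min_r2`` and positive
    slope is selected (ties broken by R²).  Returns a ``no_growth`` flag
    when no window qualifies.
    """
    t = curve.times_min
    od = curve.od600 - blank
    usable = (od >= od_lo) & (od <= od_hi)
    if usable.sum() < min_points:
        return DoublingFit(None, None, None, 0, True, "too few points in OD gate")
    y = np.full(od.shape, np.nan)
    y[usable] = np.log2(od[usable])

    best = None  # (span, r2, slope, i, j)
    n = t.size
    # contiguous usable runs
    run_start = None
    runs = []
    for i in range(n + 1):
        if i < n and usable[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            runs.append((run_start, i - 1))
            run_start = None
    for lo, hi in runs:
        for i in range(lo, hi - min_points + 2):
            for j in range(hi, i + min_points - 2, -1):
                span = j - i
                if best is not None and span < best[0]:
                    break  # shorter than the incumbent; try next start
                slope, _, r2 = ols_line(t[i : j + 1], y[i : j + 1])
                if slope > 0 and r2 >= min_r2:
                    cand = (span, r2, slope, i, j)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
                    break  # longest window for this start found
    if best is None:
        return DoublingFit(None, None, None, 0, True, "no log-linear window")
    span, r2, slope, i, j = best
    return DoublingFit(
        doubling_time_min=1.0 / slope,
        window_min=(float(t[i]), float(t[j])),
        r_squared=r2,
        n_points=span + 1,
        no_growth=False,
    )


def normalize_doubling(sample_min: float, reference_min: float) -> float:
    """Doubling time normalized to a reference strain/condition."""
    if reference_min <= 0:
        raise ValueError("reference doubling time must be positive")
    return sample_min / reference_min


@dataclass
class ProportionResult:
    """Binomial proportion with its standard error sqrt(p(1-p)/n)."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 <= self.k <= self.n):
            raise ValueError("require 0 <= k <= n")

    @property
    def p(self) -> float:
        return self.k / self.n

    @property
    def se(self) -> float:
        return float(np.sqrt(self.p * (1.0 - self.p) / self.n))


def proportion_with_se(k: int, n: int) -> ProportionResult:
    """Proportion k/n with the standard error of the proportion."""
    return ProportionResult(k=k, n=n)
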