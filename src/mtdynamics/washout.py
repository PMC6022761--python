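"""Tubulin-washout analysis.

Washout initiation is the first time point whose background fluorescence is
significantly lower (a k·σ rule; σ is a robust noise estimate) than the
mean of the previous three points; termination is found symmetrically.
Catastrophe after washout is called by sliding 5-point linear regressions:
the first window whose slope is steeper than −150 nm·s⁻¹ marks the
catastrophe, and the slow/fast depolymerization rates are the regression
slopes before/after that point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._stats import median_ci, ols_line
from .invitro import to_subunits_per_s
from .trace import LengthTrace

__all__ = [
    "WashoutDetection",
    "WashoutResult",
    "detect_washout",
    "prewashout_rate",
    "detect_catastrophe",
    "phase_rates",
    "analyze_washout",
    "summarize_washouts",
]


@dataclass
class WashoutDetection:
    """Washout window from the background series; ``found`` is False when no
    significant drop exists (distinct from an error)."""

    found: bool
    t_init_s: Optional[float] = None
    t_term_s: Optional[float] = None

    @property
    def duration_s(self) -> Optional[float]:
        if not self.found:
            return None
        return self.t_term_s - self.t_init_s


@dataclass
class WashoutResult:
    """Per-microtubule washout measurements (Fig 3-style P/D/S/F)."""

    t_init_s: float
    t_term_s: float
    prewashout_rate_um_min: Optional[float]
    t_cat_s: Optional[float]
    has_slow_phase: bool
    slow_rate_um_min: Optional[float]
    fast_rate_um_min: Optional[float]
    excluded_zero_slow: bool = False

    @property
    def washout_duration_s(self) -> float:
        return self.t_term_s - self.t_init_s

    @property
    def delay_s(self) -> Optional[float]:
        if self.t_cat_s is None:
            return None
        return self.t_cat_s - self.t_init_s

    @property
    def slow_rate_subunits_s(self) -> Optional[float]:
        if self.slow_rate_um_min is None:
            return None
        return to_subunits_per_s(self.slow_rate_um_min)

    @property
    def fast_rate_subunits_s(self) -> Optional[float]:
        if self.fast_rate_um_min is None:
            return None
        return to_subunits_per_s(self.fast_rate_um_min)


def _robust_sigma(x: np.ndarray) -> float:
    """Robust noise SD from first differences (insensitive to one step)."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_washout(
    background: Sequence[float],
    dt_s: float = 1.0,
    k: float = 3.0,
) -> WashoutDetection:
    """Find the washout window in a background-fluorescence series.

    ``t_init`` is the first sample below the mean of the previous three by
    more than ``k`` times the robust pre-drop noise SD; ``t_term`` is the
    first sample at or after ``t_init`` that is no longer significantly
    above the mean of its three successors (the drop has finished).
    """
    b = np.asarray(background, dtype=float)
    if b.size < 5:
        raise ValueError("need at least 5 background samples")
    sigma = max(_robust_sigma(b), 1e-9 * max(abs(b).max(), 1.0))
    thr = k * sigma

    t_init_idx = None
    for i in range(3, b.size):
        if b[i - 3 : i].mean() - b[i] > thr:
            t_init_idx = i
            break
    if t_init_idx is None:
        return WashoutDetection(found=False)

    t_term_idx = b.size - 1
    for j in range(t_init_idx, b.size - 3):
        if b[j] - b[j + 1 : j + 4].mean() <= thr:
            t_term_idx = j
            break
    return WashoutDetection(
        found=True, t_init_s=t_init_idx * dt_s, t_term_s=t_term_idx * dt_s
    )


def prewashout_rate(
    trace: LengthTrace, t_init_s: float, window_s: float = 10.0
) -> float:
    """OLS polymerization rate (μm·min⁻¹) over the ``window_s`` seconds
    before washout."""
    sel = (trace.times_s >= t_init_s - window_s - 1e-9) & (
        trace.times_s <= t_init_s + 1e-9
    )
    if trace.times_s[sel].size < 2 or trace.times_s[0] > t_init_s - window_s + 1e-9:
        raise ValueError(f"need {window_s} s of trace before washout")
    slope, _, _ = ols_line(trace.times_s[sel], trace.lengths_um[sel])
    return slope * 60.0


def detect_catastrophe(
    trace: LengthTrace,
    t_init_s: float,
    threshold_nm_s: float = 150.0,
    window: int = 5,
    anchor: str = "start",
) -> Optional[float]:
    """First time the 5-point regression slope exceeds the loss threshold.

    Windows of ``window`` frames slide forward from the washout; catastrophe
    is called at the first window whose OLS slope is < ``-threshold_nm_s``
    (in nm·s⁻¹).  The reported time is the window's first frame by default
    (``anchor``: ``start`` | ``center`` | ``end``).  Returns None when no
    window qualifies.
    """
    if threshold_nm_s <= 0:
        raise ValueError("threshold_nm_s must be positive")
    start = int(np.searchsorted(trace.times_s, t_init_s - 1e-9))
    n = len(trace)
    if n - start < window:
        raise ValueError(f"need at least {window} frames after washout")
    y_nm = trace.lengths_um * 1000.0
    for i in range(start, n - window + 1):
        slope, _, _ = ols_line(trace.times_s[i : i + window], y_nm[i : i + window])
        if slope < -threshold_nm_s:
            if anchor == "start":
                j = i
            elif anchor == "center":
                j = i + window // 2
            elif anchor == "end":
                j = i + window - 1
            else:
                raise ValueError("anchor must be start|center|end")
            return float(trace.times_s[j])
    return None


@dataclass
class PhaseRates:
    slow_rate_um_min: Optional[float]
    fast_rate_um_min: Optional[float]
    has_slow_phase: bool
    excluded_zero_slow: bool


def phase_rates(
    trace: LengthTrace,
    t_init_s: float,
    t_cat_s: Optional[float],
    seed_length_um: float = 0.0,
    pixel_size_nm: float = 65.0,
) -> PhaseRates:
    """Slow ([washout, catastrophe]) and fast ([catastrophe, seed]) rates.

    Slopes are OLS magnitudes in μm·min⁻¹.  The slow phase is absent when
    the catastrophe coincides with the washout; a slow rate of exactly zero
    is flagged ``excluded_zero_slow`` (such microtubules are excluded from
    rate summaries).  The fast segment ends at the first frame within one
    pixel of the seed length.
    """
    t = trace.times_s
    y = trace.lengths_um
    slow = None
    excluded = False
    has_slow = t_cat_s is not None and t_cat_s > t_init_s + 1e-9
    if has_slow:
        sel = (t >= t_init_s - 1e-9) & (t <= t_cat_s + 1e-9)
        if sel.sum() >= 2:
            slope, _, _ = ols_line(t[sel], y[sel])
            slow = abs(min(slope, 0.0)) * 60.0
            if slow == 0.0:
                excluded = True
        else:
            has_slow = False

    fast = None
    if t_cat_s is not None:
        after = np.flatnonzero(t >= t_cat_s - 1e-9)
        at_seed = after[
            y[after] <= seed_length_um + pixel_size_nm / 1000.0 + 1e-12
        ]
        start_idx = after[0]
        # fit ends at the last frame still above the seed: the frame that
        # has already arrived sits on the hold plateau, not the fast line
        end_idx = at_seed[0] - 1 if at_seed.size else len(t) - 1
        end_idx = max(end_idx, start_idx + 1)
        if end_idx - start_idx >= 1:
            slope, _, _ = ols_line(
                t[start_idx : end_idx + 1], y[start_idx : end_idx + 1]
            )
            fast = abs(min(slope, 0.0)) * 60.0
    return PhaseRates(
        slow_rate_um_min=slow,
        fast_rate_um_min=fast,
        has_slow_phase=bool(has_slow and not excluded),
        excluded_zero_slow=excluded,
    )


def analyze_washout(
    trace: LengthTrace,
    background: Sequence[float],
    seed_length_um: float = 0.0,
    k: float = 3.0,
    threshold_nm_s: float = 150.0,
    window: int = 5,
    prewashout_window_s: float = 10.0,
    pixel_size_nm: float = 65.0,
) -> Optional[WashoutResult]:
    """Full per-microtubule washout pipeline; None when no washout is found."""
    det = detect_washout(background, dt_s=trace.frame_interval_s, k=k)
    if not det.found:
        return None
    try:
        pre = prewashout_rate(trace, det.t_init_s, window_s=prewashout_window_s)
    except ValueError:
        pre = None
    t_cat = detect_catastrophe(
        trace, det.t_init_s, threshold_nm_s=threshold_nm_s, window=window
    )
    rates = phase_rates(
        trace, det.t_init_s, t_cat, seed_length_um, pixel_size_nm=pixel_size_nm
    )
    return WashoutResult(
        t_init_s=det.t_init_s,
        t_term_s=det.t_term_s,
        prewashout_rate_um_min=pre,
        t_cat_s=t_cat,
        has_slow_phase=rates.has_slow_phase,
        slow_rate_um_min=rates.slow_rate_um_min,
        fast_rate_um_min=rates.fast_rate_um_min,
        excluded_zero_slow=rates.excluded_zero_slow,
    )


def summarize_washouts(results: Sequence[WashoutResult]) -> dict:
    """Cohort summary: fraction without a slow phase (with SE of the
    proportion) and medians with order-statistic 95% CIs for delay and the
    slow/fast rates.  Zero-slow microtubules are excluded from the slow-rate
    and delay summaries, mirroring the exclusion rule of the source assay.
    """
    if len(results) == 0:
        raise ValueError("need at least one washout result")
    n = len(results)
    without = sum(1 for r in results if not r.has_slow_phase)
    p = without / n
    se = float(np.sqrt(p * (1 - p) / n))
    out = {
        "n": n,
        "n_without_slow": without,
        "frac_without_slow": p,
        "se_without_slow": se,
        "n_excluded_zero_slow": sum(1 for r in results if r.excluded_zero_slow),
    }
    delays = [r.delay_s for r in results if r.has_slow_phase and r.delay_s is not None]
    slows = [
        r.slow_rate_subunits_s
        for r in results
        if r.has_slow_phase and r.slow_rate_subunits_s is not None
    ]
    fasts = [r.fast_rate_subunits_s for r in results if r.fast_rate_subunits_s]
    for name, vals in (("delay_s", delays), ("slow_subunits_s", slows), ("fast_subunits_s", fasts)):
        if vals:
            med, lo, hi = median_ci(vals)
            out[f"median_{name}"] = med
            out[f"ci_{name}"] = (lo, hi)
    return out
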