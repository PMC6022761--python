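"""Astral-microtubule event classification and switching statistics.

Events are defined by a three-rule criterion: at least three contiguous
data points producing a length change of at least 0.5 μm with a coefficient
of determination of at least 0.80.  Catastrophe frequency for a microtubule
is the number of catastrophes divided by its lifetime minus the time spent
in disassembly (rescue frequency mirrors this with assembly time
subtracted).  Pooled per-genotype values are summarized as medians with
order-statistic 95% CIs and compared with the Mann-Whitney U test;
proportions use Fisher's exact test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._stats import median_ci, ols_line
from .trace import LengthTrace

__all__ = [
    "InVivoEvent",
    "MicrotubuleSummary",
    "classify_events",
    "event_rate_invivo",
    "summarize_microtubule",
    "catastrophe_frequency",
    "rescue_frequency",
    "summarize_condition",
    "rank_sum_test",
    "fisher_exact_2x2",
]


@dataclass
class InVivoEvent:
    """One assembly or disassembly episode satisfying the three-rule
    criterion (>=3 points, |ΔL| >= 0.5 μm, R² >= 0.80)."""

    kind: str  # 'assembly' | 'disassembly'
    start_idx: int
    end_idx: int  # inclusive
    delta_length_um: float
    r_squared: float
    rate_um_min: float
    duration_s: float

    @property
    def n_points(self) -> int:
        return self.end_idx - self.start_idx + 1


def _fit(trace: LengthTrace, i: int, j: int):
    return ols_line(trace.times_s[i : j + 1], trace.lengths_um[i : j + 1])


def classify_events(
    trace: LengthTrace,
    min_points: int = 3,
    min_delta_um: float = 0.5,
    min_r2: float = 0.80,
) -> list[InVivoEvent]:
    """Greedy maximal-window scan for assembly/disassembly events.

    From each unconsumed index the window is extended while the running OLS
    fit keeps R² >= ``min_r2``, the slope sign stays constant, and the
    local trend of the trailing ``min_points`` samples does not reverse
    (the guard that stops extension at a switch point, where the running
    fit alone would coast through on the strength of the preceding run);
    the window is emitted as an event if it has >= ``min_points`` points
    and a first-to-last length change of >= ``min_delta_um``.  Consecutive
    events may share a single boundary frame (the turning point); interiors
    never overlap.
    """
    n = len(trace)
    if n < min_points:
        raise ValueError(f"trace must have at least {min_points} points")
    events: list[InVivoEvent] = []
    i = 0
    while i <= n - min_points:
        j0 = i + min_points - 1
        slope0, _, r2 = _fit(trace, i, j0)
        if slope0 == 0.0:
            i += 1
            continue
        sign = 1.0 if slope0 > 0 else -1.0
        j = j0
        good_js = [j0] if r2 >= min_r2 else []
        while j + 1 < n:
            tail_slope, _, _ = _fit(trace, j + 2 - min_points, j + 1)
            if tail_slope * sign < 0:
                break
            slope, _, r2_next = _fit(trace, i, j + 1)
            if slope * sign <= 0:
                break
            j += 1
            if r2_next >= min_r2:
                good_js.append(j)
            elif good_js and j - good_js[-1] > min_points:
                break  # fit quality is not recovering; stop extending
        # the emitted window is the longest R²-qualifying extension that
        # also clears the length-change rule (the very last frames may sit
        # on the turn and erode ΔL)
        chosen = None
        for jg in reversed(good_js):
            dl = float(trace.lengths_um[jg] - trace.lengths_um[i])
            if abs(dl) >= min_delta_um and dl * sign > 0:
                chosen = (jg, dl)
                break
        if chosen is not None:
            jg, dl = chosen
            _, _, r2_final = _fit(trace, i, jg)
            dt = float(trace.times_s[jg] - trace.times_s[i])
            events.append(
                InVivoEvent(
                    kind="assembly" if sign > 0 else "disassembly",
                    start_idx=i,
                    end_idx=jg,
                    delta_length_um=dl,
                    r_squared=r2_final,
                    rate_um_min=abs(dl) / dt * 60.0,
                    duration_s=dt,
                )
            )
            i = jg  # turning point may start the next event
        else:
            i += 1
    return events


def event_rate_invivo(event: InVivoEvent, frame_interval_s: float) -> float:
    """|ΔL| divided by the event duration in seconds, times 60."""
    span = event.end_idx - event.start_idx
    return abs(event.delta_length_um) / (span * frame_interval_s) * 60.0


@dataclass
class MicrotubuleSummary:
    """Per-microtubule event bookkeeping and switching frequencies."""

    lifetime_s: float
    time_in_assembly_s: float
    time_in_disassembly_s: float
    n_catastrophes: int
    n_rescues: int
    assembly_rates_um_min: list
    disassembly_rates_um_min: list
    assembly_durations_s: list
    disassembly_durations_s: list

    @property
    def catastrophe_freq_per_min(self) -> float:
        # a microtubule spending its whole lifetime in disassembly has no
        # time at risk of catastrophe; it contributes zero
        if self.lifetime_s <= self.time_in_disassembly_s:
            return 0.0
        return catastrophe_frequency(
            self.n_catastrophes, self.lifetime_s, self.time_in_disassembly_s
        )

    @property
    def rescue_freq_per_min(self) -> float:
        if self.lifetime_s <= self.time_in_assembly_s:
            return 0.0
        return rescue_frequency(
            self.n_rescues, self.lifetime_s, self.time_in_assembly_s
        )


def summarize_microtubule(
    trace: LengthTrace,
    events: Optional[Sequence[InVivoEvent]] = None,
    renucleation_margin_um: float = 0.2,
    **cfg,
) -> MicrotubuleSummary:
    """Count catastrophes/rescues and phase times from classified events.

    A catastrophe is a transition from an assembly event or an unclassified
    interlude into a disassembly event (and symmetrically for rescues); two
    back-to-back events of the same kind sharing a boundary frame do not
    produce a switch.  An assembly event that starts within
    ``renucleation_margin_um`` of zero length is regrowth from the
    nucleation site, not a rescue of a depolymerizing microtubule, and is
    not counted as one.  Unclassified gaps count toward the lifetime but
    not toward either phase.
    """
    if events is None:
        events = classify_events(trace, **cfg)
    events = sorted(events, key=lambda e: e.start_idx)
    n_cat = n_res = 0
    prev = None
    for ev in events:
        if ev.kind == "disassembly":
            if ev.start_idx > 0 and not (
                prev is not None
                and prev.kind == "disassembly"
                and prev.end_idx == ev.start_idx
            ):
                n_cat += 1
        else:
            if (
                ev.start_idx > 0
                and trace.lengths_um[ev.start_idx] > renucleation_margin_um
                and not (
                    prev is not None
                    and prev.kind == "assembly"
                    and prev.end_idx == ev.start_idx
                )
            ):
                n_res += 1
        prev = ev
    return MicrotubuleSummary(
        lifetime_s=trace.duration_s,
        time_in_assembly_s=sum(e.duration_s for e in events if e.kind == "assembly"),
        time_in_disassembly_s=sum(
            e.duration_s for e in events if e.kind == "disassembly"
        ),
        n_catastrophes=n_cat,
        n_rescues=n_res,
        assembly_rates_um_min=[e.rate_um_min for e in events if e.kind == "assembly"],
        disassembly_rates_um_min=[
            e.rate_um_min for e in events if e.kind == "disassembly"
        ],
        assembly_durations_s=[e.duration_s for e in events if e.kind == "assembly"],
        disassembly_durations_s=[
            e.duration_s for e in events if e.kind == "disassembly"
        ],
    )


def catastrophe_frequency(
    n_catastrophes: int, lifetime_s: float, time_in_disassembly_s: float
) -> float:
    """Catastrophes per minute of non-disassembly time."""
    denom_min = (lifetime_s - time_in_disassembly_s) / 60.0
    if denom_min <= 0:
        raise ValueError("lifetime must exceed time spent in disassembly")
    return n_catastrophes / denom_min


def rescue_frequency(
    n_rescues: int, lifetime_s: float, time_in_assembly_s: float
) -> float:
    """Rescues per minute of non-assembly time."""
    denom_min = (lifetime_s - time_in_assembly_s) / 60.0
    if denom_min <= 0:
        raise ValueError("lifetime must exceed time spent in assembly")
    return n_rescues / denom_min


def summarize_condition(summaries: Sequence[MicrotubuleSummary]) -> dict:
    """Pooled condition row: medians with order-statistic 95% CIs.

    Rates and durations pool all events across microtubules; switching
    frequencies are per-microtubule values.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one microtubule")
    pools = {
        "poly_rate_um_min": [r for s in summaries for r in s.assembly_rates_um_min],
        "depoly_rate_um_min": [
            r for s in summaries for r in s.disassembly_rates_um_min
        ],
        "poly_duration_s": [d for s in summaries for d in s.assembly_durations_s],
        "depoly_duration_s": [
            d for s in summaries for d in s.disassembly_durations_s
        ],
        "catastrophe_freq_per_min": [
            s.catastrophe_freq_per_min for s in summaries
        ],
        "rescue_freq_per_min": [s.rescue_freq_per_min for s in summaries],
    }
    out = {"n_microtubules": len(summaries)}
    for name, vals in pools.items():
        if vals:
            med, lo, hi = median_ci(vals)
            out[f"median_{name}"] = med
            out[f"ci_{name}"] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# statistical comparisons


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a, with midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return ra - a.size * (a.size + 1) / 2.0


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sample Mann-Whitney U test with midrank tie handling.

    Exact enumeration of all group assignments when both groups have at
    most ``exact_max_n`` observations; the tie-corrected normal
    approximation otherwise.  Returns ``(U, two_sided_p)`` with U computed
    for the first sample.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u_obs = _u_statistic(a, b)
    if a.size <= exact_max_n and b.size <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        m = a.size
        const = m * (m + 1) / 2.0
        us = np.array(
            [sum(ranks[i] for i in comb) - const
             for comb in itertools.combinations(range(pooled.size), m)]
        )
        n_total = us.size
        p_le = np.sum(us <= u_obs + 1e-9) / n_total
        p_ge = np.sum(us >= u_obs - 1e-9) / n_total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_obs), float(p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u_obs), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (sum of hypergeometric
    tables with probability <= that of the observed table)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        ft = t.astype(float)
        if np.any(ft < 0) or np.any(ft != np.round(ft)):
            raise ValueError("counts must be non-negative integers")
        t = ft.astype(int)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
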