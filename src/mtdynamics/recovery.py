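"""Parameter-recovery benchmark cohorts.

Each function simulates a cohort under fixed study conditions, runs the
corresponding analysis pipeline end to end, and returns the summary
statistic the assay reports.  These are the package's self-checks: the
generator's ground truth is chosen to match published summary values, so a
correct pipeline should recover them.

Study conditions (fixed here, discussed in the methods note):

* in vitro depolymerization cohorts: 200 traces of 600 s at 1-s sampling
  with 50-nm length noise; untreated-like tubulin grows at 1.0 μm/min with
  catastrophe hazard 0.3 min⁻¹ and shrinks at 18.41 μm/min; subtilisin-
  treated (S-tubulin-like) grows at 1.5 μm/min, hazard 0.6 min⁻¹, shrinks
  at 8.57 μm/min.
* washout cohort: 200 protocols, growth 1.2 μm/min for 180 s (microtubules
  are then a few μm long, as in the source kymographs), slow phase
  1.2 μm/min for a uniform 5-40-s delay, then fast shrinkage; 1-s frames,
  50-nm length noise; the background series is a field average and is
  rendered noiseless.
* astral-microtubule cohort: 100 traces of 600 s at 4-s sampling, growth
  26.5 nm/s, shrinkage 46.7 nm/s, catastrophe hazard 0.0167 s⁻¹, rescue
  hazard 0.0278 s⁻¹, 50-nm length noise.
"""

from __future__ import annotations

import numpy as np

from .invitro import segment_phases, to_subunits_per_s
from .invivo import classify_events, summarize_microtubule
from .simulate import (
    DIParams,
    WashoutProtocol,
    add_measurement_noise,
    simulate_length_trace,
    simulate_washout_trace,
)
from .washout import analyze_washout

__all__ = [
    "UNTREATED_LIKE",
    "S_TUBULIN_LIKE",
    "WILDTYPE_ASTRAL",
    "recover_depolymerization_median",
    "recover_washout_slow_median",
    "recover_astral_dynamics",
]

#: Untreated porcine-tubulin-like in vitro kinetics (μm/min, events/min).
UNTREATED_LIKE = DIParams(
    v_grow=1.0, v_shrink=18.41, f_cat=0.3, f_res=0.0, seed_length_um=0.5
)
#: Subtilisin-digested (β-CTT-removed) tubulin: faster growth, earlier
#: catastrophe, slower depolymerization.
S_TUBULIN_LIKE = DIParams(
    v_grow=1.5, v_shrink=8.57, f_cat=0.6, f_res=0.0, seed_length_um=0.5
)
#: Wild-type yeast astral microtubule kinetics (Table-1-like ground truth).
WILDTYPE_ASTRAL = DIParams(
    v_grow=26.5 * 60.0 / 1000.0,
    v_shrink=46.7 * 60.0 / 1000.0,
    f_cat=0.0167 * 60.0,
    f_res=0.0278 * 60.0,
    seed_length_um=0.0,
)

NOISE_SD_UM = 0.05  # sub-pixel length-measurement noise at 65-nm pixels


def _child_seeds(seed: int, tag: int, n: int) -> np.ndarray:
    rng = np.random.default_rng([seed, tag])
    return rng.integers(0, 2**31 - 1, size=2 * n)


def recover_depolymerization_median(
    params: DIParams,
    n_traces: int = 200,
    seed: int = 1,
    duration_s: float = 600.0,
    dt_s: float = 1.0,
):
    """Median depolymerization-event rate (subunits·s⁻¹) from phase
    segmentation of a simulated cohort.

    Returns ``(median_subunits_per_s, n_events)``.
    """
    seeds = _child_seeds(seed, 11, n_traces)
    rates: list[float] = []
    for i in range(n_traces):
        tr = simulate_length_trace(params, duration_s, dt_s, int(seeds[2 * i]))
        tr = add_measurement_noise(tr, NOISE_SD_UM, int(seeds[2 * i + 1]))
        for ev in segment_phases(tr):
            if ev.kind == "shrinkage":
                rates.append(ev.rate_um_min)
    return to_subunits_per_s(float(np.median(rates))), len(rates)


def recover_washout_slow_median(n_traces: int = 200, seed: int = 1):
    """Median slow (pre-catastrophe) depolymerization rate after washout,
    in subunits·s⁻¹, from the full washout pipeline.

    Returns ``(median_subunits_per_s, n_with_slow_phase)``.
    """
    seeds = _child_seeds(seed, 23, n_traces)
    delay_rng = np.random.default_rng([seed, 29])
    pre = DIParams(v_grow=1.2, v_shrink=18.41, f_cat=0.0, f_res=0.0, seed_length_um=0.5)
    slows: list[float] = []
    for i in range(n_traces):
        protocol = WashoutProtocol(
            t_washout_s=180.0,
            delay_s=float(delay_rng.uniform(5.0, 40.0)),
            v_slow=1.2,
            v_fast=18.41,
        )
        trace, background, _ = simulate_washout_trace(
            pre, protocol, 300.0, 1.0,
            rng_seed=int(seeds[2 * i]),
            noise_sd_um=NOISE_SD_UM,
        )
        res = analyze_washout(trace, background, seed_length_um=0.5)
        if res is not None and res.has_slow_phase and res.slow_rate_subunits_s:
            slows.append(res.slow_rate_subunits_s)
    return float(np.median(slows)), len(slows)


def recover_astral_dynamics(n_traces: int = 100, seed: int = 3):
    """Three-rule classification of a simulated astral-microtubule cohort.

    Returns a dict with the pooled median polymerization and
    depolymerization rates (μm/min) and the cohort median per-microtubule
    catastrophe and rescue frequencies (events/min), plus counts.
    """
    seeds = _child_seeds(seed, 37, n_traces)
    poly, depoly, cat_freqs, res_freqs = [], [], [], []
    n_events = 0
    for i in range(n_traces):
        tr = simulate_length_trace(WILDTYPE_ASTRAL, 600.0, 4.0, int(seeds[2 * i]))
        tr = add_measurement_noise(tr, NOISE_SD_UM, int(seeds[2 * i + 1]))
        events = classify_events(tr)
        n_events += len(events)
        summary = summarize_microtubule(tr, events)
        poly.extend(summary.assembly_rates_um_min)
        depoly.extend(summary.disassembly_rates_um_min)
        cat_freqs.append(summary.catastrophe_freq_per_min)
        res_freqs.append(summary.rescue_freq_per_min)
    return {
        "median_poly_rate_um_min": float(np.median(poly)),
        "median_depoly_rate_um_min": float(np.median(depoly)),
        "median_catastrophe_freq_per_min": float(np.median(cat_freqs)),
        "median_rescue_freq_per_min": float(np.median(res_freqs)),
        "n_microtubules": n_traces,
        "n_events": n_events,
    }
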