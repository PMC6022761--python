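"""Astral-microtubule dynamics in cells plus culture-level statistics.

Classifies simulated astral-microtubule traces with the three-rule
criterion (>=3 points, >=0.5 um, R^2 >= 0.80), tabulates median rates and
switching frequencies with order-statistic CIs, compares two genotypes with
the Mann-Whitney U test, and fits a doubling time from an OD600 curve.
"""

import numpy as np

from mtdynamics import GrowthParams, simulate_growth_curve
from mtdynamics.growth import fit_doubling_time, normalize_doubling, proportion_with_se
from mtdynamics.invivo import rank_sum_test, summarize_condition, summarize_microtubule
from mtdynamics.recovery import WILDTYPE_ASTRAL, recover_astral_dynamics
from mtdynamics.simulate import add_measurement_noise, simulate_length_trace

cohort = recover_astral_dynamics(n_traces=40, seed=3)
print("wild-type-like cohort (40 microtubules, 600 s at 4-s frames):")
print(f"  median polymerization rate: {cohort['median_poly_rate_um_min']:.2f} um/min "
      f"(ground truth 1.59)")
print(f"  median catastrophe frequency: "
      f"{cohort['median_catastrophe_freq_per_min']:.2f} events/min "
      f"(hazard 1.00; the 0.5-um event rule hides short excursions, "
      f"so this estimate sits well below the hazard)")

# genotype comparison: slower-depolymerizing mutant vs wild type
mutant = WILDTYPE_ASTRAL.__class__(
    v_grow=WILDTYPE_ASTRAL.v_grow, v_shrink=0.6 * WILDTYPE_ASTRAL.v_shrink,
    f_cat=WILDTYPE_ASTRAL.f_cat, f_res=WILDTYPE_ASTRAL.f_res,
)
wt_rates, mut_rates = [], []
for i in range(40):
    for params, sink in ((WILDTYPE_ASTRAL, wt_rates), (mutant, mut_rates)):
        tr = add_measurement_noise(
            simulate_length_trace(params, 600.0, 4.0, 500 + i), 0.05, 600 + i
        )
        sink.extend(summarize_microtubule(tr).disassembly_rates_um_min)
u, p = rank_sum_test(wt_rates, mut_rates)
print(f"depolymerization, wild type vs mutant: "
      f"medians {np.median(wt_rates):.2f} vs {np.median(mut_rates):.2f} um/min, "
      f"Mann-Whitney p = {p:.2g}")

# growth assay: magnesium-sensitive mutant doubles half as fast
wt = fit_doubling_time(simulate_growth_curve(
    GrowthParams(od0=0.1, doubling_time_min=90.0, noise_sd=0.004), rng_seed=1))
mut = fit_doubling_time(simulate_growth_curve(
    GrowthParams(od0=0.1, doubling_time_min=180.0, noise_sd=0.004), rng_seed=2))
print(f"doubling times: {wt.doubling_time_min:.0f} and {mut.doubling_time_min:.0f} min; "
      f"normalized ratio {normalize_doubling(mut.doubling_time_min, wt.doubling_time_min):.2f}")

# nocodazole scoring: cells with astral microtubules
r = proportion_with_se(62, 80)
print(f"astral-microtubule-positive cells: {100 * r.p:.0f}% +/- {100 * r.se:.1f}%")
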