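# mtdynamics

Analysis of microtubule dynamic instability from time-lapse fluorescence
imaging, with a matched synthetic-data generator so that every stage of the
pipeline can be validated by parameter recovery.

Microtubules stochastically switch between persistent polymerization and
rapid depolymerization ("dynamic instability"). The package implements the
complete quantitative workflow used to characterize this behavior in vitro
(TIRF imaging of microtubules grown from stabilized GMPCPP seeds) and in
vivo (GFP-labeled astral microtubules in budding yeast):

- **Simulation** (`mtdynamics.simulate`) — a memoryless two-state model:
  growth at velocity *v*<sub>g</sub>, shrinkage at *v*<sub>s</sub>, with
  exponential switching hazards *f*<sub>cat</sub> (catastrophe, while
  growing) and *f*<sub>res</sub> (rescue, while shrinking); plus a TIRF
  renderer (Gaussian PSF, Poisson/Gaussian noise, taper-convolved plus
  ends), washout protocols, and exponential OD600 growth curves.
- **Image pipeline** (`mtdynamics.kymo`) — seed detection by thresholding,
  phase-correlation drift registration, rotation/crop/max-projection into
  kymographs, and intensity-threshold length tracking.
- **In vitro rates** (`mtdynamics.invitro`) — sliding-window phase
  segmentation; per-event rates from first/last points; polymerization rate
  vs tubulin concentration by OLS, with the apparent on-rate constant
  *k*<sub>on</sub> = slope x 1750 / 60 subunits·μM⁻¹·s⁻¹ (≈1,750 αβ-dimers
  per μm of 14-protofilament lattice); length-at-catastrophe CDFs.
- **Washout analysis** (`mtdynamics.washout`) — washout detection from
  background fluorescence (k·σ drop rule), catastrophe calling by iterative
  5-point regressions against a 150 nm·s⁻¹ loss threshold, and the
  pre-washout (P), delay (D), slow (S) and fast (F) phase measurements.
- **Tip structure** (`mtdynamics.tip`) — plus-end intensity decays fit with
  I(x) = background + amplitude · S((x − μ)/σ), S the standard Gaussian
  survival function; σ is the **tip SD**, a proxy for taper length.
- **In vivo dynamics** (`mtdynamics.invivo`) — the three-rule event
  criterion (≥3 contiguous points, |ΔL| ≥ 0.5 μm, R² ≥ 0.80); catastrophe
  frequency = catastrophes / (lifetime − time in disassembly); medians with
  order-statistic 95% CIs; Mann–Whitney U and Fisher exact tests.
- **Cell assays** (`mtdynamics.growth`) — doubling times from the maximal
  log-linear window of OD600 curves; binomial proportions ± SE.

The intended users are cytoskeleton labs quantifying microtubule behavior
from TIRF or spinning-disk movies, and anyone needing a tested reference
implementation of these estimators.

## Worked example

`examples/03_washout.py` simulates 60 tubulin-washout experiments (growth
at 1.2 μm/min, slow phase 1.2 μm/min for a random 5–40 s delay, then fast
shrinkage at 18.41 μm/min, 1-s frames, 50-nm tracking noise) and runs the
full detection chain:

```
washouts analyzed: 60
without a slow phase: 3% +/- 2.3% (SE of the proportion)
median slow rate: 34.8 subunits/s (95% CI 33.8-36.4); ground truth 35 — the off-rate survives the full detection chain
median delay to catastrophe: 20 s
```

The slow-phase rate approximates the tubulin off-rate: 1.2 μm/min × 1750
subunits/μm ÷ 60 = 35 subunits·s⁻¹, and the pipeline recovers it to within
1%. The other scripts in `examples/` walk through movie rendering and
tracking (01), concentration fits and rate constants (02), tip-taper
fitting (04), and in vivo classification plus growth assays (05).

A thin CLI mirrors the library for batch use: `mtdynamics simulate`,
`mtdynamics dynamics`, `mtdynamics washout`, `mtdynamics invivo`,
`mtdynamics growth` (see `mtdynamics --help`).

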