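# Methods

## The two-state model

Dynamic instability is modeled as a continuous-time, memoryless two-state
process. A growing microtubule elongates at constant velocity
*v*<sub>g</sub> (μm·min⁻¹) and catastrophes with hazard *f*<sub>cat</sub>
(min⁻¹); a shrinking one shortens at *v*<sub>s</sub> and is rescued with
hazard *f*<sub>res</sub>. Waiting times are exponential; velocities carry
no age- or length-dependence and there is no pause state. This is the
minimal model whose parameters are exactly the four quantities the
analysis pipeline estimates (two velocities, two switching frequencies),
which is what makes end-to-end parameter recovery a meaningful test.
Consequences worth keeping in mind: phase durations and excursion sizes
are exponential, so very short excursions are common — more common than in
real data, where catastrophes tend to be followed by substantial
shortening. This matters for the event-classification analyses below.

Seed boundary. Length never falls below the stabilized seed. The default
behavior is hold-and-regrow: on reaching the seed the microtubule
immediately resumes growth (in vitro, GMPCPP seeds renucleate; the rescue
hazard does not apply at the boundary). A `renucleate=False` mode
terminates the trace instead. Both are exposed because rate statistics
near the boundary depend on the choice; all shipped analyses use
hold-and-regrow.

Implied stationary behavior used as a test oracle: away from the boundary
the fraction of time spent growing is *f*<sub>res</sub>/(*f*<sub>cat</sub>
+ *f*<sub>res</sub>), and length-at-catastrophe is exponential with rate
*f*<sub>cat</sub>/*v*<sub>g</sub> for growth runs that start at the seed.

## Image formation

The renderer draws a line source of constant density (`photons_per_um`,
default 500 photons per μm per frame) from the seed to the tip,
convolved with a Gaussian PSF (default σ = 130 nm, a 1.49-NA TIRF
objective at ~500 nm emission). The plus end may be tapered: lattice
occupancy falls off as the Gaussian survival function with SD
`tip_sd_nm`, so the rendered axial edge is S((x − tip)/σ_eff) with
σ_eff² = tip_sd² + σ_PSF² (the convolution of a Gaussian-survival edge
with a Gaussian PSF is exact; the two-edge product used for the finite
segment is exact up to terms of order exp(−L²/2σ²), negligible at all
rendered lengths). Calibration defaults: 65-nm pixels; 3-s frames for in
vitro dynamics, 1-s for washouts, 4–5-s for astral microtubules. Noise
models: `poisson` (shot noise on expected counts) or `gaussian` (additive
read noise, default SD 2 counts). A movie renderer places the same model
along an arbitrary axis in a two-channel field (immobile seed channel +
dynamic channel) with optional stage drift.

What the generator does not emulate: photobleaching, uneven illumination,
out-of-focus light, microtubule crossings and bundles, speckle from
labeled-fraction statistics, and camera fixed-pattern noise. Tests passing
on this synthetic data show the estimators are correct for clean,
single-microtubule geometry; they do not certify robustness to those
artifacts.

## Length measurement noise

Analyses of simulated traces add i.i.d. Gaussian length noise with SD
50 nm (sub-pixel at 65-nm pixels), the scale of threshold-based tip
localization at typical TIRF SNR. This is the "moderate noise" condition
used by all recovery benchmarks.

## Kymographs and tracking

Frames are registered to the first frame by phase correlation on the seed
channel (the seeds are fiducial); each frame is rotated about the seed
centroid so the axis is horizontal (bilinear), cropped ±4 pixels about the
axis, and max-projected to one row. Length per frame is the distance from
the seed end to the farthest contiguous above-threshold pixel; a gap of
more than one below-threshold pixel terminates the microtubule (speckle
guard). The default threshold is global Otsu; fixed-value and
background + k·σ rules are selectable and recorded in outputs. The
measured length uses the half-pixel edge convention (seed-span edge to
far-pixel center + ½ px), which centers the discretization error; frames
entirely below threshold report length 0 with a flag. On noiseless
renders, tracked length agrees with ground truth to ≤1 px except when the
extension is shorter than about one PSF width (those frames are flagged).

## Phase segmentation (in vitro)

Each frame is classified by the OLS slope of a centered 5-frame window:
growth above +0.1 μm·min⁻¹, shrinkage below −100 nm·s⁻¹; maximal runs of
one class with ≥3 frames become events, and the event rate is the
first-to-last length change over the duration. The shrink threshold is
chosen by a bracket rule: above ~3σ of the window-slope noise and above
the mixed-slope band of windows straddling a switch point (≈ *v*<sub>s</sub>/2),
and below the slowest depolymerization velocity of scientific interest
(subtilisin-treated tubulin shrinks at ~143 nm·s⁻¹, so a threshold above
that would select only the noise tail and bias the median upward). With
the window straddling rule, event endpoints land on the first/last sample
strictly inside the linear regime, which is what keeps first-to-last rates
unbiased. Known behavior: at 1-s sampling and 50-nm noise the +0.1
μm·min⁻¹ growth threshold sits below the slope-noise floor, so slow-growth
events fragment and their first-to-last rates are biased high by endpoint
selection; growth-rate analyses should use ≥3-s sampling (the acquisition
interval of the dynamics assays), where the bias is within a few percent.

## Washout analysis

Washout initiation is the first background sample below the mean of the
previous three by more than k·σ (k = 3; σ is a robust noise SD from
median absolute first differences), termination the first subsequent
sample no longer significantly above its three successors. The background
series is treated as a field average, so its frame-to-frame noise is
small; note that the k·σ rule's false-trigger rate per frame is
scale-free (≈0.5% at k = 3), so very long pre-washout spans with
uncorrelated background noise will eventually mis-trigger — k is
configurable for such data. Catastrophe is the first 5-frame window (1-s
frames) whose OLS slope is below −150 nm·s⁻¹, timed at the window's first
frame (window-center and window-end conventions are selectable). Because
the qualifying window straddles the true switch, the call leads the true
catastrophe by up to ~2 frames; the delay statistic inherits a
corresponding small negative bias while the slow-phase fit stays clean.
The slow rate is the OLS slope from washout to catastrophe (absent when
they coincide; exact zeros are flagged and excluded from rate summaries),
the fast rate from catastrophe to the last frame above seed + 1 px — the
frame that has already arrived at the seed sits on the hold plateau, not
on the fast line, and is excluded so that the noiseless fit is exact.

## Tip-taper fitting

Axial profiles (mean or max over ±halfwidth rows) are fit with
I(x) = b + A·S((x − μ)/σ) by Levenberg–Marquardt. Initialization: μ at the
half-maximum crossing, σ from the 16th–84th-percentile crossings, A and b
from plateau and tail means; crossings are located on a 5-pixel-smoothed
profile so single-pixel noise cannot fake an early decay. The fit window
is the decay region (95% to 5% of the normalized amplitude) padded by 10
pixels on each side. Flat or rising profiles return `converged=False`
with a reason; σ pinned at its lower bound is flagged. The fitted σ
contains the PSF; both raw σ (default, matching the assay's stated
method) and the quadrature-corrected √max(σ² − σ_PSF², 0) are reported.
At amplitude-to-noise 5 the per-fit spread is large (IQR ~150 nm for
σ = 400 nm), but the median over many time points is within ~3% of truth.
Tip SD is paired with an instantaneous polymerization rate from a
centered 5-frame sliding slope for rate-binned summaries.

## In vivo event classification

An event is ≥3 contiguous points whose first-to-last length change is
≥0.5 μm with OLS R² ≥ 0.80. The scanner is greedy: from each unconsumed
index it extends the window while the running fit keeps R² ≥ 0.80 and the
slope sign is constant, with a local guard — extension stops when the
trailing 3 samples trend against the event sign — because on long events
the running fit otherwise coasts several frames past a switch on the
strength of the preceding run. The emitted window is the longest
R²-qualifying extension that also clears the 0.5-μm rule (the final
frames may sit on the turn and erode ΔL). Adjacent events may share the
turning-point frame. A brute-force oracle that enumerates every
qualifying window ships in the test suite and agrees with the scanner to
within 2 frames on single-switch traces.

Catastrophes are transitions into a disassembly event from an assembly
event or an unclassified interlude; rescues mirror this, except that an
assembly event starting within 0.2 μm of zero length is regrowth from the
nucleation site (spindle pole body), not a rescue. Frequencies divide the
per-microtubule counts by (lifetime − time in the opposite phase), in
minutes; unclassified gaps count toward lifetime only.

Structural undercount. Under the memoryless model, shrink-excursion sizes
are exponential; at wild-type-like parameters (*v*<sub>s</sub> = 2.80
μm·min⁻¹, *f*<sub>res</sub> = 1.67 min⁻¹, mean excursion 1.68 μm) about
26% of excursions fall below the 0.5-μm rule, and boundary truncation
plus 4-s sampling raise the undetectable fraction to ~40%. The recovered
median catastrophe frequency on such a cohort is therefore ≈0.55
events/min against a generating hazard of 1.0 — the classifier recovers
essentially every catastrophe that produces a classifiable event
(measured ceiling ≈0.56). Real astral-microtubule data evidently do not
have exponential excursion sizes at these parameters; recovering a
printed frequency of 1.0 with the same criterion implies nearly all real
excursions exceed 0.5 μm. Users fitting the two-state model to published
frequencies should treat the classifier-derived frequency as a lower
bound on the hazard, or correct by the detectability factor
exp(−0.5·*f*<sub>res</sub>/*v*<sub>s</sub> [μm·min units]).

## Statistics

Medians carry order-statistic (binomial) 95% CIs; per-concentration and
per-bin means carry t-based 95% CIs; proportions carry √(p(1−p)/n). The
Mann–Whitney U test uses midranks with exact enumeration when both groups
have ≤8 observations and the tie-corrected normal approximation
otherwise; Fisher's exact test is the standard two-sided hypergeometric
sum (delegated to scipy, with an independent enumeration oracle in the
tests). Rate-vs-concentration lines are OLS through pooled event-level
points (per-concentration means with CIs are reported alongside); the
x-intercept is the apparent critical concentration. Doubling times come
from the longest contiguous log2(OD) window with R² ≥ 0.99 inside an OD
gate (default 0.02–1.0), at least 10 points, positive slope; ties prefer
higher R². Exact on noiseless exponentials; with a lag phase the maximal
window can absorb a sliver of lag and shift the estimate by up to ~10%.

## Benchmark study conditions

The recovery benchmarks (`mtdynamics.recovery`, used by
`scripts/acceptance.py`) fix these conditions: in vitro depolymerization —
200 traces, 600 s at 1-s frames, 50-nm noise; untreated-like tubulin
*v*<sub>g</sub> = 1.0 μm·min⁻¹, *f*<sub>cat</sub> = 0.3 min⁻¹,
*v*<sub>s</sub> = 18.41 μm·min⁻¹; S-tubulin-like *v*<sub>g</sub> = 1.5,
*f*<sub>cat</sub> = 0.6, *v*<sub>s</sub> = 8.57 (faster growth, earlier
catastrophe, slower shrinkage). Washout — 200 protocols, growth 1.2
μm·min⁻¹ for 180 s (microtubules are then ~3.6 μm, comparable to the
assay's kymographs; much shorter microtubules leave a fast phase too
brief for the 5-point window), slow phase 1.2 μm·min⁻¹ for a uniform
5–40-s delay, fast 18.41; noiseless field-averaged background. Astral —
100 traces, 600 s at 4-s frames, *v*<sub>g</sub> = 26.5 nm·s⁻¹,
*v*<sub>s</sub> = 46.7 nm·s⁻¹, *f*<sub>cat</sub> = 0.0167 s⁻¹,
*f*<sub>res</sub> = 0.0278 s⁻¹, 50-nm noise. These sizes keep the full
benchmark run under half a minute while leaving the cohort medians stable
to ~1% across seeds.

## Known limitations

- No pause state, no age-dependent catastrophe, no GTP-cap or
  protofilament-level mechanics in the simulator.
- The renderer is 2-D and single-microtubule; no bundles or crossings.
- Catastrophe-frequency estimates from the three-rule classifier are
  lower bounds under heavy-tailed-small excursion statistics (above).
- The washout background rule is a per-frame significance test; it is not
  a changepoint model and can mis-trigger on long noisy series.
- Tracking lengths below ~1 PSF width are flagged rather than measured.
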