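# Methods

This note records the models, parameter choices and numerical decisions
behind `strainlink`, in the order the pipeline runs them.

## Synthetic experiment generator

The generator stands in for raw microcosm video. It emulates four
things: (i) logistic density-dependent growth with strain- and
treatment-specific parameters, (ii) per-cell movement and morphology
distributions that shift with treatment, (iii) dark-field imaging
(bright ellipses on a black background, 10 s bursts at 10 fps, 100
frames per 810 µL sample), and (iv) counting noise in density
estimates.

**Growth.** Populations follow dN/dt = N(µ + αN), realized through the
closed-form logistic solution rather than discrete stepping, because
the downstream regression (pcgr on N_start) is exactly this ODE's
short-interval linearization; the closed form makes parameter recovery
well-posed and exactly reproducible. Degenerate branches (α = 0, µ = 0)
use their own closed forms.

**Default demography.** Where the source experiments do not print
generative values, defaults were fixed once from ciliate biology and a
bias budget (below): *Colpidium* µ = 0.8/day, K = 5000 cells/mL;
*Tetrahymena* µ = 1.2/day, K = 10000 cells/mL (these imply roughly 7
and 5 days from dilute inocula to carrying capacity). Strains within a
species differ by ±10% in µ and −10…+10% in K; temperature raises µ
(0.02–0.035 per °C) and atrazine lowers it (0.003–0.006 per µg/mL),
additively — the temperature × pollutant product term defaults to 0.
Driver effects on α exist only in the faster species and only for some
strains.

**Assay schedule and the bias budget.** Starting densities are 20–80%
dilutions of a source culture at 75% of K, sampled at days 0, 0.25 and
0.5. These values come from an explicit error budget: the pcgr
regression estimates a secant, not the tangent, so its intercept and
slope are biased relative to (µ, α) by an amount growing with µ·Δt and
N₀/K. Mapping that bias surface (noiselessly, against the exact
logistic) shows that with one common interval per assay, biases stay
within −2…−6% over µ ∈ [0.6, 1.5] at this schedule, while fold-changes
remain large enough to measure against counting noise. Two
consequences follow. First, interval selection is per replicate assay
(the median fold-change across its dilution microcosms decides among
t0→t1, t0→t2, t1→t2, preferring the earliest whose median fold ≥ 1.5,
else the largest): mixing intervals across dilutions within one curve
introduces kinks in pcgr vs N_start that inflate slope bias several
fold. Second, sampling twice within the first day is what keeps the
linearization honest for organisms this fast.

**Counting noise.** A density observation is a count in the imaged
volume: Poisson around density × volume, gamma-mixed to a negative
binomial with overdispersion θ = 1000 (Var = m + m²/θ), representing
cells clustering despite mixing. The θ value sets a ~3% CV floor that
(a) is realistic for replicate pipetting and clustering and (b) makes
the total noise roughly homoscedastic across the 4× density range,
which matters for inference (below).

**Traits and walkers.** Each counted cell draws (speed, linearity,
size, shape) from normal distributions truncated to admissible ranges
(speed ≥ 0, linearity ∈ (0,1], size > 0, aspect ≥ 1). Trait means
drift linearly with time in treatment — a strain-specific baseline
drift plus per-driver coefficients — so index responses over the
growth interval carry strain and treatment signal; within-strain SD is
per-individual plasticity, fixed over a burst. For rendering, each
cell swims a correlated random walk: constant step length speed/fps
(so gross displacement over duration equals the drawn speed exactly)
and von Mises turning angles with concentration chosen by inverting
E[net/gross] ≈ sqrt((1+c)/((1−c)n)) so the walk's straightness matches
the drawn linearity; walls reflect. Frames are 8-bit, cells painted at
grey 200 over Gaussian read noise (SD 8), origin top-left, x right / y
down, times = frame/fps.

**What the generator does not emulate.** Illumination gradients,
focus drift, debris and artefacts, cell division or death within a
burst, density-dependent trait change, and resource dynamics. Passing
tests therefore demonstrate correctness of the inference chain under
the stated noise model, not robustness to every imaging pathology of
real video.

## Tracking

Detection thresholds at grey 100 (half the cell intensity), gates
connected components by area ∈ [20, 5000] px² and fitted-ellipse
aspect ∈ [1, 10]. Linking is greedy globally-nearest-neighbour:
candidate (track, detection) pairs ranked by distance, bound by
max_step = 15 px per elapsed frame and max_gap = 6 missed frames, with
ties broken by distance, then track id, then canonical (x, y) scan
order — detections are sorted within frames first, so output is
invariant to detection order. A Hungarian optimal-assignment mode
exists for comparison. QC keeps tracks with duration ≥ 3 s, net
displacement ≥ 5 px and detection frequency ≥ 0.5. These defaults were
tuned once against rendered ground truth (the analogue of per-species
manual fine-tuning in real pipelines): at 20 cells per 512² burst they
give ~100% cell recovery (union coverage of planted tracks), trajectory
counts within a few percent, and mean-speed error ~1%. Missed frames
inside a gap are linearly interpolated for gross displacement only;
detection frequency counts true detections.

**Linearity convention.** Speed is gross displacement over duration.
Linearity defaults to net/gross ∈ [0, 1] with 1 = straight, so that
"high linearity = straight swimming" holds and the index's flee
interpretation is coherent; the literal gross/net variant (≥ 1,
increasing with tortuosity) is available via
`linearity_convention="gross_over_net"`. A motionless track has
linearity 1 by convention (maximally straight).

## Demography

One pooled OLS of pcgr on N_start per condition across replicates.
The covariance estimator defaults to HC3 (heteroscedasticity-robust):
counting noise gives pcgr a variance that falls with density, and
classical OLS standard errors understate the intercept's uncertainty
enough to push nominal-95% CI coverage for µ below 80% in calibration;
with HC3 plus the θ noise floor, coverage sits near 92%. Classical
errors remain available (`cov_type="nonrobust"`).

Influence exclusion follows a two-criterion rule: Cook's distance ≥
0.5 (the border contour of standard diagnostic plots) **and**
|externally studentized residual| ≥ 2.0, at most 2 removals per curve
(most extreme Cook's D first), never leaving fewer than 3 points, then
exactly one refit. Excluded points remain available to the trait data.
A quadratic-term t-test on each curve is reported as a nonlinearity
screen; it never alters the fit.

K = −µ/α with the first-order delta-method variance computed verbatim
from the estimator moments. Estimates below −400 (configurable) are
flagged invalid as positive density dependence. Calibration against
10⁶-draw Monte Carlo shows the first-order formula within 5% of the
true ratio variance while CV(α) ≲ 8%, degrading smoothly to ~7% error
at CV(α) = 10% — a truncation property of the Taylor expansion, not of
the implementation; the validation suite asserts both the 5% region
and the bounded degradation.

## Trait index

The standardization pool of a species is the set of its sample-level
trait means at the time points contributing to the density-dependence
curves (both endpoints of each assay's chosen interval); pool moments
are frozen before any Δ is computed. The index applies ±1 weights to
species z-scores of the sample trait means. The index *variance* of a
sample is not uniquely defined by the study description; the default
sums species-scaled within-sample trait variances (the index variance
under within-sample trait independence, since all weights are ±1). An
alternative per-trajectory mode (index per cell, then moments across
cells) is provided; it additionally captures trait covariances.
Neither is claimed canonical. Responses are end − start differences
over the demography interval, which the response builder enforces by
construction.

## Driver models

Sequential (Type I) sums of squares in a fixed term order — N_start,
Atrazine, Temperature, Strain, their two-ways and three-way, then each
term × N_start for the demography model; the same factor order without
density terms for index responses. Temperature and atrazine enter as
unordered categorical factors (df = 2 each). Partial η² =
SS_effect/(SS_effect + SS_residual) for every term. Type III (with
sum-to-zero contrasts) is exposed as an option since the SS type of
the original analysis is not stated; on the balanced designs used here
the main-effect SS coincide. Replicate is carried but not modelled.

## Linkage

µ and α are z-scored within species over that species' 27 conditions;
K over its K-valid conditions only. Δmean/Δvariance are averaged over
every surviving replicate × dilution cell. The model family is Null
plus {Mean, Variance} × {common slope; + strain, strainC or strainT
intercepts; × strain, strainC or strainT slopes}, where strainC keeps
the alphabetically first species' strains distinct and pools the
other, and strainT mirrors it (realized as a 4-level factor). AICc =
n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k = p + 1 counting the
residual variance — stated explicitly so numbers are comparable across
implementations. Near-ties (ΔAICc < 1e-9) prefer fewer parameters,
then the fixed family order. Δmean and Δvariance are never combined in
one model.

## Problem sizes and determinism

The validation suite sizes its experiments for a laptop-class run:
recovery over 200–300 assays, 10⁶ Monte-Carlo draws for the K
variance, 10 rendered bursts of 20 walkers for tracking fidelity, 200
seeds for linkage model recovery, 1000 permutations for the ANOVA
null. All randomness flows through one seeded generator per
experiment; identical seeds give bit-identical outputs.

## Known limitations

- The pcgr regression estimates secant parameters; the residual −2…−6%
  bias against generative (µ, α) is inherent to the method at finite
  intervals and documented rather than corrected.
- Greedy linking swaps identities when paths cross; counts and
  population-level trait means are robust to swaps, but individual
  path-level quantities (e.g. per-cell linearity at crossings) are
  not.
- The strainC/strainT codings assume exactly two species; the linkage
  family is not defined for other designs.
- Trait drift is linear in time within the measured interval; real
  acclimation dynamics saturate.
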