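# Methods

## Scope and data flow

The package analyses two-drug cytotoxicity experiments in three stages:

1. **Plate arithmetic** — raw absorbances become percent viability via
   background-subtracted normalisation to the vehicle control,
   `100·(treated − media)/(vehicle − media)`; viability becomes the
   affected fraction `fa = 1 − viability/100`.
2. **Median-effect fitting** — per drug and per trial, `(Dm, m)` are
   estimated by unweighted ordinary least squares on the linearised plot
   `log10(fa/fu)` vs `log10 D` (base-10 logarithms throughout, matching
   the method's classical presentation). The plot's correlation
   coefficient `r` is reported as a conformity diagnostic.
3. **Combination analysis** — for a constant-ratio mixture fitted on total
   molar dose, the two-term combination index, dose-reduction indices,
   isobole coordinates and curve-shift overlays are evaluated at the
   requested inhibition levels, per trial, and summarised as
   mean ± SEM across trials.

## Clipping policy

`fa` is clipped into `[ε, 1−ε]` (default ε = 0.005, configurable) before
log-linearisation; negative computed viabilities (over-kill wells reading
below the media blank) are clipped to 0 and flagged. Clipped points are
retained by default — dropping the extreme wells of a steep curve
discards real information about the plateau — but a `clip_policy =
"exclude"` option removes them, since some established implementations
exclude effects at exactly 0 or 1. Retention versus exclusion changes
fitted slopes by well under the replicate noise level in the regimes the
tests cover.

## Combination conventions

- The mixture's dose axis is the **total molar dose** `d_a + d_b`;
  component doses are the ratio split `d_i = D_tot · r_i/(r_a + r_b)`.
  Entering the mixture by one component's dose instead rescales `Dm` by a
  constant and leaves CI unchanged, so the convention is cosmetic for
  constant-ratio designs.
- CI is computed **within each trial** from that trial's three fits, then
  averaged; the SEM is the cross-trial standard error. This matches the
  convention of reporting one CI per independent experiment.
- The classification band for "additive" is CI ∈ [0.90, 1.10]
  (configurable). The conventional nearly-additive band is used because
  heat-map conventions vary; values below are labelled synergism, above
  antagonism.
- The classic **two-term** (mutually exclusive) CI is computed; the
  three-term mutually-nonexclusive variant is deliberately not
  implemented.
- Sequential schedules are metadata for endpoint analysis (total exposure
  is identical); the generator can modulate the planted interaction per
  schedule to emulate regimen-dependent outcomes.
- Equipotent design ratios round the potency ratio `Dm_b/Dm_a` to the
  nearest multiple of ten, half-up (59.33 → 1:60); a `nearest_int` rule is
  available, and ratios that would round to zero fall back to the nearest
  positive integer so equal potencies give 1:1.

## The additivity null and its limits

For a **sham combination** (a drug paired with itself) CI = 1 at every
effect level, for any ratio and any `(Dm, m)` — an algebraic identity the
test suite verifies to 1e−6 over random parameters.

For a genuine pair, the Loewe-additive constant-ratio mixture is itself a
median-effect curve **exactly when both agents share the slope m** (the
mixture's `Dx` is then the ratio-weighted harmonic mean of the agents',
with the same exponent). In that case the fitted CI equals 1 to solver
precision, and the acceptance checks of the additivity null use an
equal-slope pair for this reason.

When the slopes differ, the additive mixture's median-effect plot is
convex (local slope rising from the shallower agent's m at low effect to
the steeper agent's m at high effect), and a straight-line fit introduces
a deterministic, design-dependent bias in the CI even on noise-free data.
For the package's default study conditions (m = 2 and m = 1 agents near
equipotent mixing) the bias measured across the default 8-point series is
about −6% at the 50% level and +8% at the 90% level; a 2-fold dilution
series pushes the 50%-level bias to −12%. This is an intrinsic property
of the linearised method, not of this implementation; it is the main
reason recovery tolerances for planted interactions are 10% rather than
noise-limited.

A related transform effect biases the slope estimate on noisy data: the
logit is convex above fa = 0.5 and concave below, so symmetric viability
noise at extreme effects stretches the plot outward (Jensen's
inequality), inflating `m̂` by ~6% at 3 viability points of per-well noise
on the default design (~2–4% at 2 points). Dm is much less affected
because the distortion is roughly antisymmetric about the midpoint.

## Synthetic data: what it emulates, and what it does not

`SyntheticTruth` defaults define the emulated study: a steep nanomolar
agent (Dm = 6 nM, m = 2) and a ~60-fold less potent, shallower one
(Dm = 356 nM, m = 1); 8-dose quarter-log (10^0.2 ≈ 1.585-fold) serial
dilutions centered on each curve's own midpoint (a 25-fold span keeping
effects within ~4–96%, the band where the linearised fit is informative);
quadruplicate wells; three independent trials; Gaussian per-well noise of
3 viability percentage points; vehicle and media-blank control wells with
plate optics of 1.10/0.10 OD.

The interaction is planted as a constant α on the Loewe sum
`d_a/Dx_a(fa) + d_b/Dx_b(fa) = α`, solved for `fa` per dose pair by root
bracketing (tolerance 1e−10, ≤200 iterations; unbracketable doses are
clipped to the working interval, i.e. the well is effectively untouched
or fully killed). By construction the surface's true CI equals α at every
achieved effect level, which is what makes generate→fit→CI a closed-loop
recovery test.

Features of real data deliberately **not** modelled: edge effects and
spatial plate gradients, heteroscedastic or non-Gaussian absorbance error,
pipetting serial-dilution error (correlated dose misspecification),
pharmacokinetics of sequential dosing (schedule effects enter only as an
α multiplier), and effect-level-dependent interaction α(fa). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated error model, not robustness to systematic assay artefacts.

Kinetic traces: the vehicle grows logistically (rate 0.04 h⁻¹ toward 6×
the treatment-time index over a 7-day window sampled every 30 min);
drugged wells multiply that growth by a survival term. Three modes:

- `logistic_kill` — survival is a variable-slope sigmoid in dose with
  `IC50(t′) = ic50_ref · t_ref / t′` (dose × time reciprocity): each time
  slice is an exact four-parameter logistic, giving the time-resolved
  IC50 estimator an exact oracle and a strictly decreasing IC50(t′).
- `direct_kill` — exponential kill `exp(−k·d^h·t′)`: monotone decline,
  never above vehicle.
- `senescence` — the direct-kill term delayed by a 36-h lag, times a
  transient Gaussian cell-size bump (peak 24 h, width 10 h) that lifts
  the index above the vehicle before the decline: the DNA-damage-like
  signature of agents that enlarge cells before killing them.

All generators are pure functions of (truth, seed) via
`numpy.random.default_rng` seeded with structured keys; reruns are
byte-identical.

## Time-resolved IC50

At each requested time the normalized cell index is regressed on log10
dose with a four-parameter logistic: top anchored to the vehicle's level
at that time (optionally free), bottom bounded at 0, slope free within
(0.05, 20). Time points with no half-effect crossing in the observed
response range, no dose gradient (spread < 5% of the vehicle level), or a
non-convergent optimiser are **flagged undefined** rather than
extrapolated. Treatment-time lookup uses the nearest grid point, matching
instruments that sample on a fixed cadence.

Kinetic shape classification (post-treatment, against the vehicle on a
common grid): a *rise* is ≥5% above the vehicle sustained ≥2 h; a
*decline* is a drop below 80% of the treatment-time level; rise + decline
→ `dna_damage_like`, decline alone → `direct_kill`, neither with the
trace inside ±20% of the treatment level → `cytostatic`, otherwise
`none`. Thresholds are configurable; the decision rule is monotone in the
rise threshold (raising it can only demote `dna_damage_like`).

## Problem sizes and numerical choices

The default verification workloads are sized for a laptop-class single
core: recovery tests use 100 simulated experiments per interaction level
(8 doses × 4 replicates × 3 trials each) and complete in seconds;
property-based identity checks use 1000 random parameter draws at 1e−9
tolerance. Root solving uses Brent's method; the median-effect OLS is
closed-form; 4PL fits use bounded Levenberg–Marquardt/trust-region least
squares with a mid-grid initial IC50 and unit slope.

## Known limitations

- The CI linearisation bias for unequal-slope pairs (above) means fitted
  CI values inherit a few-percent systematic error that depends on the
  dose design; conclusions near the additivity band edge should rest on
  replicate SEMs, not point values.
- Endpoint analysis cannot distinguish sequential-schedule mechanisms;
  schedules are labels unless kinetic data are analysed.
- The checkerboard summary reports margin-relative enhancement flags, not
  a response-surface interaction model.
- No Bliss-independence, HSA or ZIP scoring, and no three-term
  (mutually-nonexclusive) CI.
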