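# Methods and design notes

This note records the model, the numerical choices and their rationale, what
the synthetic data do and do not emulate, and the known limitations. It
documents how the code computes things; every number quoted in the README is
printed by the examples or the test suite at run time.

## Generative model

For subject *j*, region *r*, observation time *t* in years from the
subject's baseline visit:

    y_jr(t) = f_r(t + d_j) + s_r * nu_j + eps_jr(t),  eps ~ N(0, sigma_r^2)

- **Time reparameterization** is a pure shift: `tau_j(t) = t + d_j`, one
  latent disease time per subject shared by all regions. No individual rate
  parameter is modelled (see Limitations).
- **Trajectories** `f_r` are monotone nondecreasing in disease time. The
  data are direction-normalized first, so "nondecreasing" covers both
  atrophying structures and the enlarging ventricles.
- **Random intercept.** `nu_j` is a scalar per subject — an overall
  anatomical size offset — loading on region *r* with the sign `s_r` that
  direction normalization applied to that region. The sign matters: flipping
  an atrophying region's axis also flips where a subject's anatomy sits
  relative to the mean. A per-region intercept variant
  (`intercept_structure="per_region"`) is available; with realistic
  between-subject anatomical variance it absorbs the cross-region contrast
  pattern that identifies the time-shift and recovers shifts far worse, so
  the shared form is the default.

## Trajectory representation and inference

`f_r(u) = w_r0 + w_r1 * u~ + sum_m w_rm phi_m(u)` — Gaussian bumps on
regularly spaced centres plus explicit constant and linear trend columns
(`u~` is the domain-scaled time). The trend columns make straight lines
exactly representable; without them a decaying RBF span flattens
nearly-linear trajectories near the domain edges. Weights get an isotropic
Gaussian prior (scale 3 standardized units) and a mean-field Gaussian
variational posterior.

**Monotonicity** is enforced at 80 virtual derivative points by penalizing
the *expected rectified negative derivative* `E[max(0, -f'(u))]` under the
variational posterior (closed form for Gaussians; weight 200). This pushes
the posterior-mean derivative nonnegative and squeezes the derivative's
posterior spread where the trajectory is flat, while leaving plateaus
admissible — a hard margin of the form `mean' > z * sd'` was tried first and
rejected because it forces strictly positive slopes everywhere and tilts
plateaus into ramps. Posterior samples are additionally projected onto the
monotone cone (isotonic regression) when they violate the tolerance of 1e-3
standardized units per grid step; with the penalty active fewer than ~2 % of
samples need projection, so the projection bias on the sample mean is below
the Monte-Carlo error at 200 samples.

**Optimization** is block-coordinate ascent on the evidence lower bound:
L-BFGS on each region's variational parameters, closed-form updates of
intercepts and noise variances, and an exhaustive grid update of each
subject's shift (step 0.1 y) jointly with its profiled intercept. Every
block update cannot decrease the objective, so the recorded ELBO trace is
nondecreasing by construction. Two additions proved necessary:

1. **Timescale line-search.** Plain alternation corrects a global error in
   the shift dispersion only geometrically slowly (curve steepness and shift
   spread trade off almost freely). At a few fixed iterations the optimizer
   proposes stretching/shrinking all shifts about their mean, refits
   everything else, and keeps the proposal only if the ELBO improves.
2. **Shift marginalization (final EM phase).** Fitting curves through point
   estimates of the shifts attenuates the fitted timescale (staging error
   blurs the time axis; the measured equilibrium on a linear-truth fixture
   was a 0.85 compression). The final sweeps treat each shift as a latent
   variable with a categorical posterior on the grid and re-solve the
   penalized curve updates under the expected design, which restores the
   scale to ~1.00. Reported shifts are the posterior means under the final
   grid posterior.

A constant also trades between the intercepts' mean and the basis constant
term; an explicit re-gauge moves it into the basis weight whenever that
raises the ELBO.

**Identifiability.** Training shifts are constrained to mean zero by an
origin offset between the user-facing timeline and the internal basis
coordinate; the time *unit* is pinned by the known 12-month visit spacing.
Initialization orders subjects by their mean standardized level
(severity); the timescale line-search makes the result insensitive to the
initial spread.

**Convergence** is declared when the relative ELBO change per outer
iteration falls below 1e-4 (warning above 1e-3). Defaults: 14 RBF centres on
a (-12, 8)-year basis domain, lengthscale 1.6x the centre spacing (~2.5 y —
smoother settings stabilize the change-point estimator, see below), 30 outer
iterations, 4 EM sweeps. A 150-subject fit takes ~8 s on one CPU.

## Anchoring

`t = 0` is defined as the disease time at which the reference trajectory
equals the manifest-HD group's baseline mean — a volumetric abnormality
threshold. The reference region is chosen automatically as the one whose
trajectory crosses its own HD mean most steeply: a trajectory already
saturated in manifest HD (the striatum) pins the crossing poorly, and using
it as reference displaced the anchor by several years in testing; the
late-accelerating ventricles localize it sharply. Anchoring applies a single
global offset (exact pass-through at the reference, idempotent) and stores
each region's own crossing time for reporting.

Because the manifest group is diagnosed *before* enrolment, its mean
baseline disease time is positive (~1.2 y in the generator), so the anchored
threshold sits past true clinical onset. This is what produces the positive
(over-)estimation of time to onset under interval censoring: the threshold
is reached ~1.2 y after onset while annual-visit detection delays the
recorded onset by only ~0.5 y on average.

## Change points and magnitudes

For each of S posterior samples per region (S = 1,000 for the headline
summaries), the change point is the grid time maximizing the discrete first
difference (grid step 0.05 y; ties break to the earliest time; flat or
exactly-linear samples are flagged undefined and excluded with a reported
count). Summaries are boxplot statistics per region. Magnitude per curve is
max − min, convertible to percent of the control mean via the HC raw mean
and residual SD stored by the adjustment model.

Grids should cover the *data-supported* span (`model.support`, the central
98 % of observed shifted times): outside it the posterior is
prior-dominated, and sampled-curve variance there creates spurious steep
segments that capture the argmax. Regions whose change point sits near the
edge of coverage (earliest/latest in the cascade) carry the largest
uncertainty — across generator seeds their recovered mean change time moves
by up to ~1–2 y, while interior regions stay within a few tenths of a year.
The trajectory smoothness default (lengthscale ~2.5 y) was chosen because
rougher trajectories make the per-sample argmax estimator unstable in
weak-gradient regions.

## Nonlinearity index

The least-squares line is fitted to the posterior-mean trajectory evaluated
at the staged observation times, and the index is the RMS
trajectory-vs-line difference over the central (2–98 %) staged-time range.
Fitting the line to the *data* instead was considered and rejected: after
shift marginalization the trajectory is de-attenuated while a line through
noisy staged times is not, so the two differ by a slope artefact unrelated
to curvature. With the curve-vs-line definition the index is a pure
curvature measure: exactly linear truths score ~0.02–0.03 standardized units
(the residual being basis wiggle, shrinking with cohort size), and steeper
logistics score strictly above shallower ones.

## Staging and onset prediction

Staging slides an individual's visit series rigidly along the posterior-mean
trajectories and returns the exact argmin over a uniform grid (step 0.05 y)
— deliberately a grid scan, testable against an independently coded
exhaustive search. The default objective profiles out the subject's shared
anatomical intercept (ridge penalty matching the model prior, signed by the
direction map) before summing squared differences; the plain
sum-of-squared-differences objective is available as `intercept="none"`.
The profiled objective is not cosmetic: with realistic anatomical variance
(ICC ~0.9) the plain objective trades the unknown offset against time along
the trajectory slope and its staging error SD is ~2 y versus ~0.25 y
profiled. Measurements outside the trajectory range saturate to the nearest
boundary with a warning.

Predicted time to onset is minus the anchored stage. Evaluation reports the
median absolute residual with quartiles, RMSE, maximum absolute error and a
descriptive OLS line of predicted on actual with a 95 % CI.

## Survival benchmark

Onset age given CAG repeat length is logistic with location
`21.54 + exp(9.556 − 0.1460·CAG)` and variance
`35.55 + exp(17.72 − 0.3269·CAG)` (constants transcribed from the benchmark
model's source publication, recorded in `SurvivalParams.provenance`;
supported CAG range 41–56, enforced). Conditioning on being event-free at
the current age uses analytic inverse-CDF truncation — deterministic per
seed, no rejection sampling — and predictions are the mean of 10^4 draws.
Invariant checks (location strictly decreasing in CAG, CDF monotone,
sampler-vs-CDF Kolmogorov–Smirnov distance, Monte-Carlo mean vs quadrature)
guard the transcription, since the parameter values cannot be asserted
against an independent source at run time.

## Cross-validation

Folds split subjects, never visits. Held-out subjects are staged with the
default staging rule, given shrunk intercepts by the training-time
estimator, and their RMS residual around the shifted trajectories is
compared with the full-data fit's residual. The ratio is ~1.02 on
well-specified cohorts of ~90 gene carriers.

## What the generator emulates — and what it does not

Emulated: group structure (HC / PreHD / manifest HD at observational-study
scale, ~100/104/80 by default), three annual visits, ten regions with
approximately sigmoidal trajectories whose change times span ~11 years with
the striatum earliest and largest (magnitudes 7–22 % of control mean) and
the ventricles as the single enlarging, late-accelerating region;
individual time-shifts spanning ~11 years with the manifest group drawn
from the late half of the span (diagnosis as a noisy threshold, slightly
overlapping the premanifest range); linear covariate effects (age, sex,
site, TIV, field strength) injected into raw volumes for the preprocessing
step to undo; a shared anatomical intercept and i.i.d. measurement noise.
The intercept/noise split (SD 0.95 / 0.3) gives a test–retest ICC of ~0.91 —
the reliability regime of longitudinally registered volumetry — and makes
the HC residual SD ~1, so generator units pass through HC z-scoring
unchanged and the configured noise SD is what the model sees.

Not emulated: image processing and its artefacts (registration error,
segmentation failure, QC exclusions), site batch effects beyond additive
offsets, missing visits (available as an option, off by default),
individual progression-rate differences, CAG-dependent progression (CAG is
drawn independently of the shift by default — deliberately, so the survival
benchmark comparison isolates what staging adds), and non-sigmoidal or
non-monotone biology. Passing recovery tests on these cohorts therefore
shows the estimator is correct under its assumptions, not that real MRI
pipelines satisfy those assumptions.

The time-shift distribution in the real studies is unknown; uniform over
the span is a generator choice, flagged as such.

## Numerical details and degenerate inputs

- Monotonicity tolerance: 1e-3 standardized units per grid step, for the
  posterior mean and every sample.
- Staging/shift grids: `lo + k*step` with the late end shrunk so a rigid
  series stays inside the fitted domain; argmin ties break to the earliest
  time.
- Change-point degeneracies: samples with maximal gradient below 1e-4 per
  step, or gradient-tied across the grid (exactly linear), are excluded and
  counted.
- Kernel density estimates of stage distributions renormalize to integrate
  to 1 on the padded grid; a zero-spread input yields a narrow Gaussian at
  the common value rather than an error.
- Single-visit-only datasets are rejected (shifts unidentifiable); a
  single-level categorical covariate or rank-deficient design is rejected
  with the offending columns named.
- Noise variances are floored at 1e-3; intercept prior scale is fixed at
  1.0 (the natural scale of z-scored data). An empirical-Bayes update of
  that scale exists but is off by default: starting from zero intercepts it
  collapses the prior and locks a compressed-timescale local optimum.

## Known limitations

- No individual-level progression rates; a subject's deviation from the
  group trajectory is absorbed by the intercept and noise.
- Change points at the edges of data coverage are biased toward the
  interior by up to ~1 y (half the transition unobserved).
- The estimated noise SD absorbs residual curve misfit; worst-region
  recovery error is typically 10–20 % at 150 subjects, occasionally just
  above 20 % on unfavourable seeds.
- Anchoring inherits the manifest group's enrolment bias: if that group is
  far past onset at baseline, `t = 0` is correspondingly late, and onset
  predictions inherit the offset (visible here as the positive residual
  under interval censoring).
- The variational posterior is mean-field over basis weights; posterior
  uncertainty bands are approximate and tend to be narrow where the
  monotonicity penalty is active.
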