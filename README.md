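# hdprogression

Monotone Gaussian-process disease progression modelling of regional brain
volumes in Huntington disease (HD): reconstruct a common disease timeline
from short-term longitudinal MRI-derived volumes, order regional atrophy by
its change points, stage unseen individuals from a single visit or a short
series, and predict time to clinical motor onset against a CAG/age survival
benchmark.

## Who this is for

Researchers modelling neurodegenerative progression from longitudinal
tabular biomarkers — here, ten covariate-adjusted regional brain volumes
(caudate, putamen, pallidum, lateral ventricles, thalamus proper,
sensory-motor, frontal, temporal, occipital, parietal) measured at three
annual visits in healthy controls (HC), premanifest gene carriers (PreHD)
and manifest HD. Because the cohort studies this design reflects are
access-controlled, the package ships a first-class synthetic cohort
generator with known ground truth, so every pipeline stage is testable
end-to-end.

## The model

Observed study time tells you little about disease stage: participants enter
at unknown points of a decades-long process. The model aligns everyone on a
latent disease timeline. For subject *j*, region *r*, at time *t* (years from
that subject's baseline):

```
y_jr(t) = f_r(t + d_j) + nu_j * s_r + eps,    eps ~ N(0, sigma_r^2)
```

- `f_r` — group-level trajectory of region *r* over disease time,
  nonparametric (Gaussian-process prior via a trend-augmented RBF basis)
  and constrained to be nondecreasing (first derivative positive), fitted
  by variational inference;
- `d_j` — the subject's *time-shift*: their disease time at the baseline
  visit, shared across regions (one latent disease time per person);
- `nu_j` — a shared anatomical random intercept, loading on each region with
  the sign `s_r` of its direction normalization;
- `sigma_r` — region-specific measurement noise.

Raw volumes are first adjusted for age, sex, site, total intracranial volume
(optionally field strength) by regressing against the HC group, z-scored
against HC, and direction-normalized so every region increases with disease
(the enlarging ventricles keep their sign; atrophying regions are flipped).

The fitted model is post-processed into the study's headline outputs:

- **anchored timeline** — `t = 0` is placed where the reference trajectory
  equals the manifest-HD baseline mean (the abnormality threshold);
- **change points** — for each of 1,000 posterior trajectory samples per
  region, the time of maximal gradient; the per-region distributions order
  the regional cascade;
- **nonlinearity index** — RMS distance between each trajectory and its best
  straight line over the staged-data range (Table-2-style ranking);
- **staging** — an unseen individual's disease time is the exhaustive-grid
  argmin of the (intercept-profiled) squared distance between their adjusted
  volumes and the mean trajectories; predicted time to onset is minus the
  stage;
- **survival benchmark** — onset age as a CAG-dependent logistic
  distribution (location `21.54 + exp(9.556 − 0.1460·CAG)`), conditioned on
  being event-free at the current age, predicted by the mean of 10^4
  truncated draws.

## Worked example

```bash
python examples/01_simulate_and_fit_timeline.py
```

generates a 250-subject cohort (100 HC, 95 PreHD, 55 HD; seed 42), fits the
model and prints:

```
time-shift recovery: Pearson r = 0.997, median |error| = 0.14 years

regional cascade (change point = time of maximal gradient ...):
  caudate              recovered  -6.13 y (true  -6.0)   magnitude  13.0 %
  putamen              recovered  -4.68 y (true  -5.0)   magnitude  16.5 %
  pallidum             recovered  -3.80 y (true  -4.0)   magnitude  16.9 %
  ...
  lateral_ventricles   recovered  +0.97 y (true  +1.0)   magnitude  20.9 %
  ...
  parietal             recovered  +5.30 y (true  +5.0)   magnitude   5.8 %
```

Each gene carrier's latent position on the timeline is recovered to a median
0.14 years from three annual visits, and the regional cascade — striatum
first, cortex later, ventricles accelerating around onset — is recovered in
the right order with change points within a year of the simulated truth.
`examples/02_stage_and_predict_onset.py` stages an unseen premanifest cohort
and compares onset prediction against the survival benchmark (staging RMSE
0.65 y vs 6.85 y when CAG carries no timing signal);
`examples/03_model_checks.py` runs cross-validation (residual ratio ~1.02),
the nonlinearity ranking and CAG-stratified refits.

## Layout

```
src/hdprogression/
  simulate.py    synthetic cohorts with ground truth (+ CSV/YAML I/O)
  preprocess.py  HC-referenced covariate adjustment and standardization
  model.py       monotone variational GP fit, sampling, cross-validation
  timeline.py    anchoring, change points, nonlinearity, CAG strata
  staging.py     staging, group densities, onset evaluation
  survival.py    CAG/age logistic onset-age benchmark
examples/        narrative scripts, one per capability
tests/           pytest suite incl. end-to-end recovery checks
docs/methods.md  modelling and design notes
```
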