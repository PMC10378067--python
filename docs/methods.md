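# Methods

This note records the models, conventions and numerical choices behind
`thermoparam`, and what the synthetic-data tests do and do not establish.

## Thermogram representation and preprocessing

All analysis operates on excess specific heat capacity (cal/°C·g) on the
canonical mesh 45.0–90.0 °C at 0.1 °C (exactly 451 points); every module
refuses curves that are not on it.  The preprocessing operations mirror the
standard DSC post-processing chain — buffer-reference subtraction, division
by total protein mass (concentration × cell volume), linear baseline
subtraction, replicate averaging, linear interpolation onto the mesh — and
are all affine in c_p, so they commute with averaging (property-tested to
1e-10).  The baseline anchor windows default to 45–50 °C and 85–90 °C: the
flat pre- and post-transition regions of plasma thermograms.  They are a
stated convention, configurable per run, since published workflows rarely
record the exact anchors used by the instrument software.  Raw instrument
files (power vs time) are out of scope; the entry point is a per-temperature
heat-capacity table.

## Summary metrics

Twenty metrics per curve; the statistical set excludes TPeak3 (see below).
Decisions where the conventions were genuinely open:

* **Peak windows** are closed intervals 60–66.9 / 67–72.9 / 73–78 °C; ties
  inside a window resolve to the lowest temperature, which makes extraction
  deterministic and keeps edge-pinned shoulder peaks reproducible.
* **Monotonic peak finding** reads "three or more rising steps then three or
  more falling steps" with strict inequalities: a plateau breaks a run.
* **Width** is the distance between the *outermost* linear-interpolated
  crossings of half the *global* maximum, i.e. a property of the whole
  denaturation envelope rather than any single peak.
* **V1.2** is the minimum strictly between TPeak1 and TPeak2; an interval
  with no interior mesh point is an error, not a silent fallback.
* **Ratios** with a zero denominator raise; baseline-corrected clinical
  curves are positive near the peaks, so this only guards degenerate input.
* **TPeak3** is computed and reported but excluded from the 23-parameter
  statistical set: at realistic geometries the third transition often
  presents as a shoulder on the second peak's tail, the windowed estimate
  pins to the window edge for most samples, and the two peak finders
  legitimately disagree there.  `compute_metric_set` records per-peak
  method agreement as flags.

Every metric is cross-checked against an independent brute-force
recomputation (pure-Python scans over mesh points) to 1e-9 on random
three-transition fixtures.

## PCA features

Column-mean-centered, unscaled PCA via SVD of the n × 451 matrix.  Scores
for PC1–PC4 join the statistical parameter set; k defaults to 5 for the
scree report.  Eigenvector signs are fixed by making each loading's
largest-magnitude element positive — the sign is otherwise arbitrary, and
survival results quoted "per unit PC3" must be read with the fitted sign,
not an assumed one.

## Status linear models

For each parameter: ordinary least squares of parameter ~ group × sex,
reduced by partial F-tests (α = 0.05; the threshold is a convention — the
source workflow states the procedure, not the cutoff) from interaction →
main effects → group only.  Residual normality (Shapiro–Wilk) and
homoscedasticity (Breusch–Pagan), both at α = 0.05, stand in for visual
QQ/residual-plot inspection; the plots are still emitted.  On failure the
chosen form is refit as a median regression (statsmodels `QuantReg`,
kernel-based asymptotic covariance), with the overall test a Wald
chi-square of all non-intercept coefficients.  Overall p-values are
BH-adjusted across the 23-parameter family, and only FDR-significant
parameters receive pairwise contrasts: estimated marginal means averaging
the sex cells with *equal* weights (the emmeans convention, not observed
frequencies), all three group differences, and a studentized-range (Tukey,
k = 3) adjustment; for interaction models the contrasts are reported within
each sex.  The grouping factor is generic, so subgroup re-analyses (cancer
location, number of affected organs, stage) reuse the module unchanged.

## NED-vs-active classification

Controls are excluded first.  Thermogram predictors pass through an
iterative VIF filter (drop the worst offender until all VIF ≤ 5 ≈ at most
80% multicollinearity; among tied maxima the later column is dropped, so
perfect collinearity removes the later duplicate).  Stepwise selection is
greedy forward/backward under AIC or BIC, accepting a step only when the
criterion strictly decreases — equal-criterion ties therefore keep the
smaller model.  Complete separation triggers a ridge-penalized refit with a
warning.  Validation is 25 repeats of stratified 5-fold cross-validation:
repeat r shuffles with seed `base + r` (the schedule is stored in the
report), rows are canonically sorted by sample id first so results are
order-invariant, held-out AUC is averaged across the 125 folds, and
threshold-0.5 confusion metrics are pooled over all out-of-fold
predictions.  The ROC band is the empirical 2.5/97.5 percentile envelope of
the per-fold ROC curves on a common grid, since no analytic band
construction is specified for this protocol.  Predicted probabilities carry
delta-method CIs on the logit scale when a coefficient covariance is
available; `calibrate_intercept` supports worked examples quoted from
coefficient tables whose intercept is unpublished — the recovered intercept
is a derived constant, not a measured one.

## Survival

Cox fits use lifelines (Efron tie handling — the standard default; the tie
method is otherwise unstated), Wald intervals, and the same BH routine as
the status stage for the univariate family.  Backward elimination uses
BIC = −2·log partial likelihood + k·ln(d) with d the event count (the
Volinsky convention for Cox models); the null partial likelihood is
recovered from the likelihood-ratio statistic, and the empty model is an
admissible endpoint.  Kaplan–Meier median splits send values exactly at the
median to the lower ("at-or-below") arm.  RMST is the exact area under the
KM step function to τ (default 8 years; τ beyond a group's last observed
time is clipped with a warning), with the Greenwood plug-in variance
Σ a_i² d_i / (n_i (n_i − d_i)), a_i the tail integral of Ŝ from t_i to τ —
implemented directly because the convenience routine in the survival
library returns the variance of min(T, τ), a different quantity.  The
implementation matches R's `survival::survfit(..., rmean=τ)` point estimate
and standard error to 10 digits on a frozen fixture.  PFS analysis applies
the univariate screen to NED records with follow-up; time is counted from
sample collection for both endpoints.

## Synthetic cohort generator

The generator emulates the *statistical structure* the pipeline assumes,
not thermodynamics: curves are three Gaussians plus white noise, with no
van 't Hoff two-state modelling.  Fixed study conditions: group sizes
49 control / 74 active / 33 NED; peak centers (63, 70, 75) °C, widths
(1.8, 1.6, 2.2) °C, amplitudes (0.26, 0.30, 0.10) cal/°C·g; measurement
noise SD 0.004; active-group T_Peak2 shift +0.4 °C; survival coefficient
β = 0.553 per unit of the latent factor; age medians 59/62/53 with the
observed ranges; group-wise sex imbalance (65.3/36.5/39.4% female).

Free parameters chosen once as conventions (not fitted to anything):

* subject-level T_Peak2 SD 0.8 °C — consistent with a ≈1 °C SD and a
  ≈4 °C observed spread in real cohorts; jitters are truncated at ±2.5 SD
  so peak centers stay inside their assignment windows;
* small center jitters for peaks 1 and 3 (0.15, 0.25 °C), 6% lognormal
  amplitude jitter per peak, 5% global intensity jitter — these place
  ≥95% of curve variance in the first five PCs, matching the low-rank
  structure of real thermogram matrices;
* melanoma peak-1 amplitude factor 0.90 (a detectable Area/Peak1 drop in
  melanoma vs control) and a 3% female peak-2 amplitude factor to exercise
  the sex terms;
* a latent z ~ N(0,1) per subject that deepens the Peak 1–2 valley
  (loading 0.015) and widens the peak-3 tail (loading 0.02) — the
  PC3-like prognostic mode — and multiplies the active-group OS hazard by
  exp(0.553·z); baseline hazards 0.12/0.05/0.03 per year for
  active/NED/control, exponential censoring tuned to a 35% censored
  fraction; NED recurrence is a null process at 0.05 events/year with 78%
  censoring (≈7 events among 32 records with PFS data; one NED record
  deliberately lacks PFS follow-up).

Under class-conditional Gaussian covariates the implied logistic slopes
are shift/variance: 0.4/0.8² = 0.625 per °C of T_Peak2 and 9/14² ≈ 0.046
per year of age; `ground_truth` records these for recovery tests.  Each
sample draws from a counter-keyed RNG substream (`default_rng([seed, i])`),
so cohorts are byte-reproducible and column-order-independent.

**What passing tests show — and don't.**  The generator's within-group
covariance is a stand-in: three jittered Gaussians plus two fixed loading
shapes, with independent subject effects.  Real thermograms have richer
correlated variation (instrument drift, concentration error, proteome
composition), so recovery and calibration results here validate the
*machinery* (estimators unbiased at the generated effect sizes, error rates
controlled under the null, fold structure correct), not the clinical effect
sizes themselves.  Cohort-specific published quantities (cross-validated
AUCs near 0.63–0.66, a 1.7-year RMST difference, per-parameter p-value
tables, the 97.7% five-PC variance share) depend on the study's own
thermogram matrix and are reproduced only when that matrix and clinical
table are supplied to the pipeline, which accepts them in the documented
CSV layouts.

## Problem sizes used in the automated checks

Simulation-based tests run at the default cohort size (156) with replicate
counts chosen for stable Monte-Carlo bounds: 200 replicates for effect
recovery and the metric oracle, 60 for null FDR calibration, 10–60 for the
remaining power and coverage checks, with acceptance thresholds keeping
≥3σ binomial slack at the expected rates.  All stochastic tests are seeded
and deterministic.

## Known limitations

* No shoulder/inflection detection beyond the two published peak finders.
* No regularized or nonlinear classifiers, no probability recalibration.
* No time-varying covariates, competing risks, or formal proportional-
  hazards tests (non-convergence and monotone-likelihood warnings are
  surfaced, not resolved).
* Quantile-regression inference relies on kernel-based asymptotic standard
  errors; small-sample median-regression p-values are approximate.
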