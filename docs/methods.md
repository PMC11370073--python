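# Methods

This note documents the models, conventions and numerical choices behind
`actitraj`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic-data validation does and does not
demonstrate.

## Signal processing and features

Raw tri-axial acceleration (default 30 Hz, units of g) is reduced to the
per-sample vector magnitude and segmented into 15-s non-overlapping
windows aligned to the recording start (not to clock minutes); a trailing
partial window is dropped. Each window yields 25 features, all computed on
the window's vector magnitude:

1–5. mean, SD, coefficient of variation, min, max
6–11. 10th/25th/50th/75th/90th percentiles, interquartile range
12–14. skewness, excess kurtosis, lag-1 autocorrelation
15–16. zero crossings of the mean-centred signal, peaks above mean + 1 SD
17–22. total spectral power, dominant frequency (Hz), power at the
dominant frequency, its fraction of total power, second dominant
frequency, normalised spectral entropy
23–25. band power 0.25–2.5 Hz, band power 2.5–5 Hz, their ratio
(ε-guarded)

Spectra come from an untapered FFT of the mean-centred window; the
dominant-frequency search excludes bins below 0.1 Hz to suppress residual
gravity leakage. Mean-centring within windows is this package's
convention; no gravity-removal filter is applied. Degenerate zero-variance
windows (constant non-wear signal) pin autocorrelation, skewness, kurtosis
and spectral entropy to 0 so the feature vector stays finite. The window
SD is carried alongside the features because non-wear detection reuses it.

Spread features scale linearly with the mean-centred signal amplitude and
the dominant frequency is scale-invariant; both properties are tested.

## Activity classification

A scikit-learn random forest with 500 trees, √25 = 5 features per split,
unlimited depth and no class weighting. Class labels are encoded as
fixed-order integers (SED < L_ACT_G < MV_ACT_G < WALK < RUN) so
prediction ties break deterministically in that order. Evaluation is
leave-one-subject-out at the child level — window-level cross-validation
would leak within-child correlation — with predictions pooled into a
single confusion matrix. "Recognition accuracy" per class is recall on
that pooled matrix; the headline score is the macro-averaged F-score. On
the default synthetic corpus the package's regression bar is macro
F ≥ 0.80 (typical values ≈ 0.95–0.97); this is a property of the
generator's difficulty, not an estimate of performance on real
recordings.

## Non-wear, daily summaries, inclusion

Non-wear is evaluated on the same 15-s windows used for classification: a
maximal run of windows with VM SD < 0.013 g (13 mg, milli-gravity) whose
span is ≥ 30 min (inclusive — exactly 120 windows qualifies) becomes a
non-wear interval. Windows inside non-wear contribute to neither behaviour
minutes nor wear time; each remaining window contributes 0.25 min to its
predicted class. Days are delimited by local calendar midnight and
recordings are split before summarisation; a detected non-wear run may
span midnight and is excluded from both adjacent days. A day is valid at
≥ 480 wear minutes; a subject-wave is included with ≥ 4 valid days of
which ≥ 1 falls on a weekend. Sleep is not modelled: synthetic protocols
place wear in waking hours and emit overnight periods as device-off.

## Guideline adherence

Three rules, all thresholds inclusive: toddlers (age < 3) total
PA ≥ 180 min/day; preschoolers (3–5, not at school) additionally
energetic play ≥ 60 min/day; school children energetic play ≥ 60 min/day.
School status dominates age, so a five-year-old already at school is
scored against the school rule. Adherence is judged on the mean across a
child's valid days (the default, matching a single per-wave binary
outcome for the logistic model); an all-days variant — every valid day
must individually meet the rule — is available behind a switch. Age is
decimal years at the end of device wear.

## Trajectory models

Minutes outcomes: linear mixed model fitted by REML (statsmodels MixedLM)
with fixed effects for sex, a restricted cubic spline in age, the
spline-by-sex interaction and optional covariates (maternal work status,
dwelling type, yard size, season, COVID-period flag as categoricals
against their first sorted level; device wear time as a continuous
covariate), plus a child-level random intercept.

The spline is the Harrell truncated-power restricted cubic basis: for
knots t₁ < … < t_k the basis is the linear term plus k−2 terms

    h_j(x) = [(x−t_j)₊³ − (x−t_{k−1})₊³ (t_k−t_j)/(t_k−t_{k−1})
              + (x−t_k)₊³ (t_{k−1}−t_j)/(t_k−t_{k−1})] / (t_k−t₁)²,

continuous through the second derivative and exactly linear outside the
boundary knots. Four knots by default, placed at the 5th/35th/65th/95th
percentiles (linear-interpolation quantiles) of the observed ages, both
overridable.

Adherence outcomes: logistic random-intercept model. The scalar random
effect is integrated out of the marginal likelihood by 25-node
Gauss–Hermite quadrature and (β, log σ) maximised by BFGS, with the full
fixed-effect covariance from the numerical Hessian. This is the same
estimator family as adaptive-quadrature GLMM tooling; on common data it
matches `lme4::glmer(nAGQ = 25)` to within optimizer tolerance (the test
suite cross-checks fitted probability curves to < 0.02 and the
random-intercept SD to < 0.05). A constant outcome (everyone meets, or
nobody does) is complete separation: the fit is returned flagged as
non-converged with no finite estimates, and marginal means refuse to
predict from it.

Marginal means are predictions on an (age, sex) grid with covariates at
representative values: the default "reference" policy holds continuous
covariates at their training-sample mean and categoricals at their
reference level; a "population" policy instead averages the design over
the observed covariate rows. Intervals are delta-method 95% CIs with
normal quantiles (a documented approximation — no small-sample df
correction; intended n is in the hundreds of children). Logistic
predictions are back-transformed to proportions after computing the
interval on the log-odds scale. Ages outside the boundary knots are
linearly extrapolated and flagged with a warning. Joint hypotheses (e.g.
the age-by-sex interaction block) use the Wald statistic βᵀV⁻¹β against a
chi-square with block-size degrees of freedom.

Numerical details: the LMM tries L-BFGS, BFGS and Powell in turn before
flagging non-convergence; an exactly interpolating fit on noise-free data
(variance components at the zero boundary) is accepted as a degenerate
converged fit. The GLMM accepts BFGS termination when the final score
sup-norm is below 1.0 (negligible relative to the likelihood curvature at
the intended sample sizes).

Design utilities: Cohen's d as delta/SD (a 5 min/day change against an SD
of 42 min/day gives d = 0.119 → 0.12), composite sums (energetic
play = walk + run + moderate-vigorous games; total PA = LPA + energetic
play), the energetic-play deficit max(0, 60 − mean MVPA), and a
normal-approximation two-sample power function for design exploration
(the power function makes no claim about paired or wave-correlated
designs).

## Synthetic data: what it emulates, what it does not

Signals are gravity baseline (1 g on the vertical axis) + Gaussian noise
+ a sinusoidal locomotion component (class-specific frequency and
amplitude) + Bernoulli one-second bursts for the moderate-vigorous games
class. Default parameters order the expected window VM SD as
SED < L_ACT_G < WALK < MV_ACT_G ≤ RUN. Corpus simulation adds per-child
lognormal variation (SD 0.30 on amplitude and noise scale, SD 0.15 on
cadence) so held-out children genuinely differ from training children.
Non-wear is emitted as an exactly constant 1 g signal — unambiguous
ground truth for the detector. None of this is physiologically realistic
biomechanics: passing tests demonstrate that the pipeline's logic and
estimators are correct on data satisfying their assumptions, not that the
classifier would reach any particular accuracy on real free-living
recordings (wrist placement, posture transitions and device calibration
error are all absent).

The cohort generator emulates a two-wave design: ages uniform on [2, 5]
at wave 1, wave 2 after a 1.5–2.5-year gap (school entry), 4–7 monitoring
days per wave with the last days of each protocol falling on weekends,
default 60% attrition at wave 2, equal sex ratio. Day values are true
mean curve + sex offset (+10 min for boys on PA outcomes by default) +
child random intercept (SD 20 min) + residual (SD 30 min); sedentary +
LPA + energetic play equals wear time exactly by construction. The
default true curves are themselves restricted-cubic-spline functions on
fixed generator knots (2.4, 3.6, 5.0, 6.4), least-squares projections of
a peak-at-five quadratic (total PA), an increasing line (energetic play)
and a U-shape (sedentary). Making the truth a member of the fitted model
family is deliberate: parameter-recovery and CI-coverage checks are then
well-posed (a truth outside the spline span would fail coverage by
construction as n grows, which would test the generator, not the
estimator). Covariates are generated with no true effect, so adjusted and
unadjusted fits estimate the same curves. Wear time is endogenous
(sedentary + total PA), so recovery checks fit without the wear
covariate; the full covariate list remains the default for the pipeline's
descriptive use.

## Problem sizes and runtime choices

Validation simulations are sized for a single CPU: CI-coverage
calibration uses 200 replicate cohorts of 120 children (coverage is
scale-free in n, so smaller cohorts probe the same property as the
package-default 500); Wald type-I error uses 500 replicates of 150
children; classifier validation uses the full default corpus (31
children, ~2,480 windows, 500 trees per LOSO fold). The end-to-end demo
pipeline runs one child-week of raw signal, a reduced training corpus and
an 80-child cohort so a full simulate-to-report pass takes well under a
minute and reruns byte-identically.

## Known limitations

- The 25-feature set is a fixed, documented package choice; other
  deployments of window-level forests use different sets.
- No autocalibration, filtering or resampling of raw signal; inputs are
  assumed clean and at the declared rate.
- Count-based non-wear algorithms (Choi, Troiano) are out of scope.
- Adherence proportions between ages two and three are not comparable
  (the rule itself changes); the package computes both but draws no
  comparison.
- CIs use normal quantiles; for very small cohorts they will be
  anti-conservative.
- The GLMM supports a single scalar random intercept (no random slopes,
  no crossed effects), matching the intended analysis.
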