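# Methods

This note documents the models, procedures, numerical choices and
limitations of `biacomp` at the level a maintainer or reviewer needs.

## Reference method: deuterium dilution

A weighed oral dose of D₂O equilibrates with all body water within a few
hours; total body water follows from the dilution principle

TBW (kg) = dose (mg) / plateau (ppm) / 1.041,

where the plateau is the enrichment rise above the participant's own
baseline, averaged over the 3 h and 4 h saliva samples, and 1.041
corrects for deuterium exchanging with non-aqueous hydrogen. Dose
volume is banded by body weight — 10 ml below 30 kg, 20 ml for 30–50 kg
(both boundaries inclusive), 30 ml above — and converted to mass with
the D₂O density 1.107 g/ml. A relative disagreement above 5 % between
the two post-dose rises sets a quality flag without excluding the assay
(both samples are retained; the protocol defines no exclusion criterion
for disagreement). Negative enrichment rises are errors, never clipped.

Fat-free mass is TBW divided by a hydration factor — the water fraction
of fat-free mass, which at these ages is taken from age/sex reference
values: 0.754 / 0.747 for boys and 0.766 / 0.755 for girls in the 11–12
and 13–14-year bands (age 13.0 falls in the second band; ages outside
[11, 15) are an error, not an extrapolation). Fat mass is weight minus
fat-free mass; a negative fat mass is flagged, not clipped, so
FFM + FM = weight holds for every result. TBW% uses the
clothing-adjusted arrival weight as denominator (scale weight minus the
0.5 kg the analyser deducts automatically); a different weight column
can be passed if a protocol weighs at the end of the visit instead.

Plausibility filtering excludes results whose TBW% is missing, strictly
above 80 % or strictly below 35 % of body weight ("over"/"under" read as
strict, so the boundary values are kept), plus participants with a
height-for-age z-score below −4 (extreme short stature outside the
target population); every exclusion carries a machine-readable reason
code.

## Candidate predictors

Exactly 23 candidates per participant, in a fixed documented order (see
`features.CANDIDATE_COLUMNS`): sex (boys = 0, girls = 1), age (y),
height (m), weight (kg), BMI, waist circumference (cm), weight loss
during the visit (kg), Tanner pubic-hair stage (1–5), three behavioural
dichotomies (transport to clinic, overnight fasting, bladder emptied;
a missing answer is coded 0.5), resistance at 50 kHz (Ω), reactance at
1/15/50/200/1000 kHz (Ω), and the height²/value indices of those six
channels (cm²/Ω). Height deliberately lives in two unit systems: the
indices use centimetres (the conventional resistance-index scale) while
the equations use metres; both columns are carried and named. Missing
values anywhere outside the three dichotomies are an error — the
pipeline refuses to impute them silently.

## Prediction models and selection

All equations are ordinary least squares. The OLS engine
(`linreg.SubsetOLS`) refits arbitrary column subsets from the centred
Gram matrix of one fixed design matrix: centring removes the intercept
and conditions the normal equations on the covariance scale, after
which each subset fit is an O(p³) solve with p ≤ 23. This is what makes
nested repeated cross-validation (~10⁵–10⁶ subset fits) run in seconds.
The engine's coefficients, standard errors and p-values are verified
against statsmodels in the test suite; statsmodels is a cross-check
oracle only, never the implementation. Rank deficiency is detected by a
scale-invariant condition-number check (threshold 10¹⁰ on the
correlation-scaled Gram matrix) and reported with the names of the
collinear columns; inside a backward path a collinear column falls back
to a pseudo-inverse fit, gets a zero t-statistic and is dropped first,
with a warning.

Three selection routes:

* **Best subsets** (BIC or AIC): exhaustive enumeration, refusing
  search spaces above 5×10⁶ subsets (the full 23-candidate space must
  use the backward route). AIC = n·ln(RSS/n) + 2k and
  BIC = n·ln(RSS/n) + k·ln n with k counting the coefficients, the
  intercept and the error variance; the additive Gaussian constant is
  omitted consistently, so values compare across fits on the same data.
  Ties break toward fewer variables, then lexicographic candidate
  order (sizes scanned upward, combinations lexicographic, strict
  improvement required). A zero RSS returns −∞ with a warning.
* **Backward elimination**: from the full candidate set, repeatedly
  drop the slope with the smallest |t|, recording the fit at every
  size. |t|-ranking is the standard choice where the original
  procedure's internals are not specified; it is isolated in one
  function should a different ranking ever be wanted.
* **RCV**: repeated k-fold cross-validation (default k = 10, 10
  repeats) of the backward path chooses the model *size*; with the
  one-SE rule the smallest size whose mean validation RMSE is within
  one standard error of the minimum is taken, where SE = SD of the
  per-split RMSEs at the minimising size divided by √(#splits). The
  chosen size is then refit on all data via the full-data backward
  path. Folds are drawn uniformly at random without sex stratification;
  all randomness flows from one `numpy` Generator, so a seed fixes the
  selection exactly. k = n (leave-one-out) is rejected by the n ≥ 2k
  precondition.

`max(p)` on a fitted equation is the largest p-value among the
non-intercept coefficients (the intercept is not a selectable variable).

Model families combine an outcome — TBW kg directly, TBW %, or TBW kg
computed as weight × (TBW % prediction)/100 — with a scope, joint (sex
as a candidate) or sex-specific (separate equations, sex dropped). The
via-percentage family fits the percentage equation and only transforms
predictions, so its selection is identical to the percentage family's.

## Out-of-sample validation

Nested repeated cross-validation: for each of `n_repeat_sets` random
k-fold splits, the complete selection procedure is rerun on each
training part (for RCV this nests a second CV inside every fold) and
the held-out fold is predicted, so no participant's outcome ever
influences the model that predicts it — a property the tests assert via
fold bookkeeping. RMSE(PE) is computed per repeat and averaged;
r²(PE) = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)² over the pooled out-of-sample
predictions. Per-sex errors are the sex-restricted residuals of the
same prediction sets, not separate runs. For plotting and agreement,
the *representative* repeat is the one whose RMSE(PE) is closest to the
average (ties to the lowest index). Bland–Altman agreement uses
differences oriented measured − predicted, bias ± 1.96·SD limits, SD
with ddof = 1.

## Synthetic cohort generator

No individual-level data accompany the study, so the generator emulates
its published structure: 86 boys and 92 girls; per-sex Gaussian
covariates at the published means/SDs (height 141/146 ± 8 cm, BMI
16.0 ± 1.4 / 16.7 ± 1.9 kg/m², resistance 440 ± 56 / 419 ± 44 Ω, five
reactance channels, age, waist, weight loss, height z-score);
Tanner-stage and behavioural-flag frequencies from the published
per-sex counts, including the published missingness rates of the three
dichotomies. Draws for physically positive covariates are resampled
(not clipped) below zero — never triggered at the defaults, which sit
>10 SD from zero; the weight-change variable is exempt because a
negative value (net fluid intake) is meaningful; age is resampled into
[11, 15). Weight is derived as BMI × height(m)², so the BMI invariant
holds exactly.

The ground truth is the published percentage equation evaluated on the
generated covariates plus Gaussian noise with SD 2.0 percentage points
— the study conditions implied by its 1.99-point out-of-sample error —
and TBW kg = TBW% × weight/100, which gives the kg outcome the
multiplicative structure that makes the via-percentage family win.
Resistance is drawn *directly* from its configured distribution and the
resistance index computed from it, rather than solving the index out of
a sampled TBW% (an alternative we evaluated): the direct draw keeps
every covariate's sample mean exactly calibrated to its configured mean
(the inverted construction biases mean resistance ~3 % low), while still
making the generating process exactly linear in the candidate set with
exogenous regressors — so OLS on a noise-free cohort recovers the
generating coefficients to ≤10⁻⁶, a test-suite invariant. Generated
TBW% is kept inside the plausible (35, 80) band by redrawing the noise
of the rare offending row; implausible and missing values enter only
through `inject_artifacts`, which flags its rows so filter-recovery
tests have ground truth.

Matching deuterium assays invert the dilution formula (plateau =
dose/(TBW·1.041)) so the round trip is exact at zero noise; the 3 h and
4 h samples then get independent Gaussian noise, default SD 5 ppm —
the upper end of the FTIR precision the protocol certifies (CV ≤ 0.55 %
of a 600–1100 ppm plateau). Baselines are Normal(150, 2) ppm around
natural deuterium abundance.

What the generator does **not** emulate: inter-covariate correlations
(the study reports none, so height, BMI and the impedance channels are
drawn independently per sex — observed TBW% variance is therefore
larger than in the real sample and in-sample r² higher), pubertal-stage
physiology, measurement drift, and any non-linearity or
heteroskedasticity of real bioimpedance data. Passing tests therefore
demonstrate that the *pipeline* recovers a known truth under the
study's noise conditions, not that the frozen equations are valid
beyond their derivation population (ages 11.5–14.5 y, stunting-
prevalent rural setting, Seca m515; the calculator warns outside
20–90 % predicted TBW and cross-checks RI against height²/R at a 1 %
tolerance).

## Problem sizes used in the test suite

Simulation-based checks use scaled problem sizes chosen to keep the
Monte-Carlo resolution comfortably finer than the effects being tested:
noise recovery runs nested CV with 10 repeat sets and 5 inner-RCV
repeats on the full 86 + 92 cohort; the model-family ordering is
averaged over 10 independently generated cohorts at 2 outer repeat
sets and 3 inner repeats (the ordering margins are ~5 %, the per-mean
MC error ~1 %); support recovery uses 100 seeded replicates; large-n
calibration uses 600 per sex. The generator's defaults themselves are
never tuned per test — they are the study conditions.

## Known limitations

* Best-subsets is plain enumeration; a branch-and-bound (leaps-style)
  search over all 23 candidates is out of scope, and BIC/AIC selection
  inside nested CV is therefore only available for reduced candidate
  sets.
* The one-SE rule's SE treats the per-split RMSEs as independent, the
  conventional (slightly anticonservative) choice.
* Sex-specific models need roughly n > 30 per sex for the inner CV of
  the full candidate set to remain well-posed; below that the backward
  path cannot start from 22 candidates and the run errors with fold
  context.
* The dilution module implements the gravimetric single-isotope plateau
  protocol only — no isotope-ratio mass spectrometry variants or
  multi-compartment kinetics.
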