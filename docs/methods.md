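# Methods

This note records the statistical model behind `sepscore`, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic data can and cannot establish.

## Outcome model

The endpoint is the combined sepsis label: a patient is a case when
infected **and**, within 72 h of ED admission, at least one of

* a sepsis-2-style acute organ dysfunction in a non-neurologic system,
* treatment in an intensive care unit, or
* death.

Neurologic dysfunction (mental status ≥ 4 on the 1–5 ordinal: drowsy or
unconscious) is tracked but never sepsis-defining, because altered mental
status is an input of every score being evaluated and would otherwise leak
the outcome into the predictors.

Default single-organ cut-offs (editable YAML, units in comments):
SBP < 90 mmHg (cardiovascular), PaO₂/FiO₂ < 300 mmHg (respiratory),
creatinine > 177 µmol/L (renal), platelets < 100·10⁹/L (hematological),
bilirubin > 34 µmol/L (hepatic). These are standard sepsis-2-era values;
any study using different laboratory thresholds can supply its own file.

**Severinghaus inversion.** PaO₂ is estimated from pulse oximetry by
inverting `SaO₂ = (23400/(PaO₂³ + 150·PaO₂) + 1)⁻¹` with Brent root
bracketing on [1, 700] mmHg (`xtol` 10⁻¹⁰; the round-trip through the
forward equation reproduces SaO₂ to ≈10⁻¹³). The conversion is applied
only where saturation still carries information about PaO₂: SaO₂ 90–94%
for non-COPD patients, and 87–95% with simultaneous oxygen therapy for
COPD patients; outside these windows the ratio is reported as absent and
respiratory dysfunction is not assessable from oximetry. FiO₂ defaults to
room air (0.21) when not recorded.

A missing laboratory value never raises: the organ flag stays `False` and
a warning is emitted. This mirrors a chart review that cannot adjudicate
an organ system without the measurement, and it makes complete-case
exclusion an explicit, visible downstream filter rather than an implicit
scoring failure.

## Scores

All scores share one structure: per variable an ordered list of bands
`(threshold, direction, points)`; a value is awarded the points of the
*most severe* band it satisfies (`max_band`), never the sum of all
satisfied bands — the convention of the NEWS family, and the only reading
under which the shipped SEWS/SHEWS point sets stay in the range their
cut-offs imply (an 85-year-old scores 5 age points, not 1+4+5=10). A
`cumulative` rule is available for sensitivity analysis. Inequalities are
strict exactly as the definitions print them (`age>45` excludes 45).

* **NEWS2** is encoded from the published chart (SpO₂ scale 1 by default;
  scale 2, for hypercapnic respiratory failure with an 88–92% target
  range, is available per record). Consciousness scores 3 for any
  mental-status level other than normal.
* **RETTS** vital-sign limits ship as an editable YAML fixture following
  the published adult triage system; the level is the worst level with any
  satisfied criterion. Symptom algorithms are represented by a single red
  override hook (the infection algorithm escalates to red on petechiae
  with concomitant infection signs); only the red/not-red dichotomy enters
  the evaluation surface.
* **SEWS/SHEWS** are the shipped derived scores with cut-offs 7 and 10.

Missing inputs contribute 0 points and are listed in
`ScoreResult.missing_inputs`.

## Score derivation

Given a cohort and outcome vector:

1. **LOWESS screening** (`statsmodels` local-linear smoother, tricube
   weights, default bandwidth 2/3, no robustifying iterations) locates the
   range of each variable where outcome risk departs from baseline. The
   smoothed-curve mode discretizes the active region (departure > 0.05
   from the smooth's minimum) at a configured step; the fixed published
   grid is also shipped: age 40–90 by 5 years, heart rate 60–140 by 5,
   SBP 70–120 by 2, DBP 40–90 by 2, respiratory rate 20–40 by 2, and the
   mental-status ordinal levels. When HBP is included its grid spans the
   clinically used 20–60 ng/mL decision range by 2 (no grid was published
   for the biomarker; this is the package's choice).
2. **Dichotomization** produces one binary indicator per (variable,
   cut-point), oriented to the risk-increasing side (age >, heart rate >,
   respiratory rate >, mental status ≥, SBP <, DBP <, HBP >); constant
   columns are dropped.
3. **Stage 1 stability selection**: for each of 50 repeats, a fresh
   stratified 10-fold split; per fold, the full L1-penalized logistic path
   (100 log-spaced penalties from the data-driven λ_max down to λ_max/100)
   is fitted and the mean CV-AUC curve computed with tie-corrected
   Mann–Whitney AUCs. The penalty maximizing mean CV-AUC is selected
   (exact ties break toward more penalization), the model is refitted on
   the full data at that penalty, and every indicator with |coefficient| ≥
   0.05 is recorded. An indicator is *included* when recorded in > 50% of
   repeats **and** its mean recorded coefficient is ≥ +0.05 (the signed
   mean filter removes wrong-sign artifacts on risk-oriented indicators).
4. **Adjacency collapsing**: among included indicators on consecutive grid
   cut-points of one variable, the smaller-coefficient one is dropped,
   iterated to a fixpoint (idempotent).
5. **Stage 2** repeats the selection on the survivors with the penalty
   chosen by the classic one-standard-error rule on the CV-AUC curve (the
   most penalized model within one SE of the optimum).
6. **Points**: integer points proportional to the stage-2 mean
   coefficients, scaled so the smallest retained coefficient maps to 1
   point (rounding half away from zero); every retained indicator scores
   ≥ 1.
7. **Cut-off**: `max single-variable points + 2`, the rule that requires
   contributions from more than one variable and regenerates both shipped
   cut-offs (7 from a maximum single contribution of 5; 10 from 8). A
   stricter `+1` rule and arbitrary callables are accepted.

**Why the stages divide the labour the way they do.** CV-AUC depends only
on the ranking of scores, so once the informative indicators have entered
the path the curve is nearly flat; the AUC-optimal penalty is weakly
identified and can land anywhere on the plateau, including dense models
whose full-data refit lets an occasional pure-noise indicator clear the
0.05 filter in many repeats. Single-stage selection frequencies are
therefore a weak noise filter by themselves. Noise exclusion is delivered
by the composition: the signed mean-coefficient filter, adjacency
collapsing, and above all the one-SE stage 2, after which pure-noise
indicators show final-stage frequencies below 0.5 (usually 0) while
planted indicators stay at 1.0. The recovery experiments measure exactly
this: stage-1 frequency for planted effects, final-stage frequency for
noise.

**Solver.** The penalized fits use a glmnet-style iteratively-reweighted
least-squares + cyclic coordinate-descent path solver (numba-compiled,
warm starts along the path, active-set sweeps with full KKT verification
passes, unpenalized intercept). It agrees with scikit-learn's SAGA
L1-logistic solutions to ~10⁻³ in every cross-check and is an order of
magnitude faster on the hundreds of cross-validation paths a derivation
run needs. Cross-validation fold paths use a looser convergence tolerance
(10⁻⁶ vs 10⁻⁸ for refits) since they only feed rank-based AUCs.

## Evaluation statistics

* Sensitivity/specificity CIs are exact Clopper–Pearson; this is the
  interval family that reproduces the published intervals (a Wilson or
  Wald interval differs in the upper bound of the screening-triage
  sensitivity cell).
* AUC is the tie-corrected Mann–Whitney statistic; its CI and the paired
  two-score comparison use the DeLong structural-component variance
  (midrank formulation). The implementation is cross-checked against R's
  `pROC` (agreement to 10⁻⁹) and a stratified bootstrap of var(ΔAUC).
  Identical score vectors are reported as difference 0, p = 1.
* Odds ratios use the Woolf logit-scale interval; a zero cell is an error
  unless a continuity correction is requested explicitly. No continuity
  correction is applied anywhere by default — this reproduces all eight
  published mortality OR cells to one decimal.
* Chi-square is Pearson's without continuity correction, 1 df.
* Reporting rounds percentages to integers and ORs to one decimal, as
  validation tables print them; raw values are retained in the
  machine-readable report. One published cell is internally inconsistent
  with its own counts (a specificity of 261/273 = 95.6% printed as 95);
  the package reports the count-faithful value.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not real ED case mix:

* Vitals are truncated normals (diastolic pressure a Beta-like fraction of
  systolic so `sbp > dbp > 0` holds by construction); mental status is an
  ordinal draw; comorbidities are independent Bernoulli flags.
* The sepsis label is drawn from a logistic model over planted threshold
  indicators of the vitals, with the intercept calibrated by root-finding
  so the realized prevalence matches the preset. With all weights zero the
  label is exactly Bernoulli(prevalence).
* HBP and lactate are log-normal conditional on the outcome class
  (right-skewed, as biomarkers are).
* Organ-dysfunction labs are arranged so the outcome recomputed by the
  labelling module agrees with the planted label end-to-end: cases without
  a vitals-driven dysfunction receive one planted lab dysfunction (or an
  ICU/death-only route at a configurable rate); infected non-cases are
  kept free of qualifying dysfunction, which requires nudging the rare
  conflicting vital out of its dysfunction range (raising an SBP below 90,
  moving a saturation out of the PF window). This slightly distorts the
  non-case tails of those marginals; it is the price of exact
  planted-label/labelling-module agreement.
* Missingness is MAR: a logistic model in observed age and the outcome
  with the intercept calibrated to the requested marginal rate; rates
  above 0.5 are rejected. Preset rates are below 7% per variable.
* One master seed; per-stage generators spawn from `SeedSequence` in a
  fixed order, so identical configs give byte-identical cohorts.

The two presets were calibrated once against the published cohort
structure (sepsis fractions 46%/30%, infected fraction 42% in the
undifferentiated cohort, median ages ≈70/52 and ≈77/72 by outcome) and are
not adjusted thereafter. What passing tests on these cohorts shows is that
the pipeline recovers known planted structure and that its statistics
agree with independent oracles; it does not show how any score performs on
real patients — measurement error, correlated comorbidity patterns,
enrolment mechanics and site effects are deliberately not modelled.

## Multiple imputation

Chained equations over the score variables, visiting in order of
increasing missingness, 10 sweeps, m = 20 completed data sets (defaults;
all configurable). Continuous and ordinal variables use predictive mean
matching: a ridge-stabilized Bayesian linear regression (coefficient and
residual-variance posterior draws) predicts the mean of each missing cell,
and the imputed value is drawn from the observed values of the k = 5
nearest-predicted donors — imputations are therefore always actually
observed, physiologically attainable values. Binary variables use a
Newton-fitted logistic model with an approximate posterior coefficient
draw and a Bernoulli draw. Comorbidity flags and the outcome are always
predictors and never imputed. Per-iteration means of the imputed cells are
recorded per variable and data set for convergence plots.

Pooling follows the literal published description — the median AUC and the
medians of the per-set DeLong CI bounds across the m sets — with Rubin's
rules (mean estimate, within+between variance) available as the principled
alternative behind a flag.

## Problem sizes and numerical choices

* Recovery experiments: n = 5000 with 50 × 10-fold repeats for the
  headline run (≈4–5 min on one CPU); unit tests use n = 2000 with 10–20
  repeats, which recovers the same structure.
* λ path: 100 values, λ_max/λ_min = 100. Deeper paths only lengthen the
  flat AUC plateau.
* Coefficient threshold 0.05, frequency threshold 0.5 (both stages);
  points rounded half away from zero.
* Empty candidate grids, degenerate outcomes (one class), fold counts
  exceeding the minority class, all-missing variables and zero 2×2 cells
  are errors with named causes, not silent results.

## Known limitations

* The published organ-dysfunction laboratory thresholds, the full RETTS
  symptom-algorithm catalogue and the exact NEWS2 chart revision were not
  printed in the source's main text; the shipped fixtures encode the
  standard published versions and are deliberately editable.
* Whether boundary values of the derived-score bands were inclusive in the
  original analysis is unknowable from the printed tables; strict
  inequalities are assumed.
* The derived-score band points are per-indicator coefficients read
  through a highest-band rule; for nested indicators of one variable the
  fitted additive model and the banded score differ slightly by
  construction. This ambiguity is inherited from the score-table format
  itself.
* Lactate is accepted as a candidate biomarker but no published grid
  exists for it; the shipped fixture omits it.
* Real-cohort discrimination (AUCs of the published study) cannot be
  reproduced because patient-level data were never deposited; all
  AUC-bearing claims here are property-based (oracle equivalence,
  parameter recovery) on synthetic data.
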