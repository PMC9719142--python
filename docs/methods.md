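# Methods

This note documents the statistical model behind `statesurv`, the design of
the synthetic-data generator, the numerical choices in the weighting and
estimation machinery, and the limits of what the package's passing tests
demonstrate about real data.

## The estimation problem

The target quantities are state-level prevalences — diagnosed and
undiagnosed diabetes in the population age 50+ with an office visit in the
past year; hypertension and high cholesterol within the diabetes
population; and ABC control (A1c, blood pressure, non-HDL cholesterol)
within the diagnosed population — estimated separately from three sources
that each fail to be a state-representative sample in a different way:

* the **national survey** has a proper national design but no state
  identifiers and no state-level representativeness;
* the **panel survey** has state identifiers but too few respondents in
  most states for direct estimation;
* the **EHR extract** is a census of its own clinics, clustered in a subset
  of counties, with biomarkers measured only when a clinician ordered them.

Each source is therefore pushed through a source-specific adjustment toward
the same state target population before estimates are compared.

## Case definitions

Two calendar windows govern classification: a *case-finding* window
(default 2010-01-01..2013-12-31) for diagnoses, prescriptions and
diagnostic labs, and a *control* window (default 2012-01-01..2013-12-31,
always contained in the former) for control assessment. The cut points are
A1c ≥ 6.5 % and FPG ≥ 126 mg/dL for undiagnosed diabetes (inclusive),
SBP ≥ 140 / DBP ≥ 90 mmHg for an elevated reading, non-HDL-C ≥ 130 mg/dL
for high cholesterol, and exclusive control targets A1c < 9 %, SBP < 140
and DBP < 90, non-HDL-C < 130. All are configurable (`CutPoints`).

Decisions taken where the rules left room:

* **Two elevated readings must fall on distinct dates.** Same-visit repeat
  readings are not independent confirmations of hypertension. A practical
  consequence: survey examinations occur on one date, so survey
  hypertension classification rests on self-report and medications, which
  is how self-report surveys actually ascertain the condition.
* **Control uses the most recent qualifying value in the control window**;
  multiple readings on that date are averaged (one measurement occasion).
* **Non-HDL-C requires a same-date TC and HDL pair.** A total cholesterol
  without a same-date HDL contributes nothing and is counted
  (`tc_without_hdl_count`).
* **EHR analysis population.** EHR patients without at least one ABC result
  in the control window are not assigned a disease status: the record-based
  method cannot see them, so they are excluded from the EHR denominators
  (`ehr_abc_filter`, on by default). Survey denominators have no such gate.
* **Gestational-only diabetes self-reports** do not count as diagnosed.
* Eligibility is age ≥ 50 (inclusive), an office visit in the past year
  (12 months ending at the configurable index date, default 2013-12-31),
  and not pregnant; an alternate `min_age=18` mode supports adult-population
  sensitivity analyses. Missing age is ineligible and counted.

Classification is a pure function of (record, history, windows, cut
points): row order never matters, and adding an elevated result can only
create cases, never remove them. On a synthetic population with perfect
recording (event sensitivity 1, all biomarkers measured, all undiagnosed
cases A1c-detectable) classification reproduces the generating truth
exactly; this oracle-equivalence property is tested.

## FPG imputation

Undiagnosed diabetes needs FPG evidence that two sources never collect. A
logistic model for P(FPG ≥ 126 | A1c, age, sex) — fitted by weighted ML on
the national FPG half-sample, restricted to persons neither diagnosed nor
A1c-positive — supplies it. The predictor set is configurable; the default
(A1c, age, sex) is deliberately small, since the model's job is to carry
the marginal elevated-FPG rate and its A1c gradient, not individual
prediction. The fit refuses pathological inputs: fewer than 30 outcome
events, constant predictor columns, or unstable coefficients (|β| > 50,
a separation symptom).

For each person lacking FPG, the elevated indicator is drawn
Bernoulli(p̂) independently in each of m completions (default m = 10).
Deterministic evidence dominates: a diagnostic A1c or an observed FPG fixes
the classification in every completion. Estimates that depend on the
undiagnosed indicator are computed per completion and combined by Rubin's
rules, T = W̄ + (1 + 1/m)B, so between-imputation uncertainty propagates
into the reported SEs (the total can never fall below the within
component). Imputation is off for the EHR source by default: its
undiagnosed classification uses observed A1c only, which is precisely the
undercount the cross-source comparison is designed to expose.

## Weighting

**Raking** multiplies weights margin-by-margin until every weighted cell
total matches its control total, with relative tolerance 1e−8 and a
500-cycle cap (IPF converges fast on well-posed margins; hitting the cap is
an error, not a warning). Margins already satisfied converge in zero
cycles; the engine validates that every person maps to a target cell and
that no positive target faces an empty sample cell. The IPF limit is
order-independent, so the configured margin order only affects iteration
count. The engine is verified against an independently coded brute-force
IPF on random problems and against the closed form on
independence-structured margins.

**Two-step EHR geographic weighting.** Step 1 post-stratifies each covered
county to its census age × sex totals — an exact ratio adjustment that
gives every covered county total weight proportional to its population.
Step 2 rakes the resulting age × sex totals to the state totals of the
office-visit population, transferring the weight of uncovered counties onto
demographically similar covered-county patients. Cells the sample cannot
support are collapsed conservatively: sex is pooled within the age band
first, and an age band with no sample merges its target into the nearest
populated band. The same collapse rule serves both steps and every collapse
is logged.

**Propensity adjustment** of the national survey toward a state stacks the
sample with a state reference sample (drawn from the state's census in the
synthetic study), fits a main-effects logistic regression of membership on
the harmonized covariates (age band, sex, race/ethnicity, insurance,
education, general health status), and multiplies base weights by the odds
p̂/(1 − p̂). Raking to the state's demographic and health-status margins
follows, then scaling so the weights sum to the state 50+ population.
Predicted probabilities at 0 or 1 abort with a non-overlap diagnostic.
Health-status and demographic margins are raked *marginally* (not jointly):
joint state cross-tabulations of demographics with health status are not
generally published, and marginal raking is what the available control
totals support.

**Panel strategy.** States with at least 500 panel respondents (inclusive
threshold, configurable) are estimated directly on their design weights;
smaller states borrow their census division's respondents and run the same
propensity + raking adjustment toward the state.

**Trimming** caps weights above median × factor (default 20) and
redistributes the excess proportionally, conserving the total; margins can
be re-raked afterwards. In the pipeline, trimming applies to the
propensity-adjusted national weights, where extreme odds factors can arise;
the EHR two-step weights are bounded by construction and are not trimmed.

After any calibration step the weighted total equals the declared
population total (within tolerance); this conservation is asserted in the
tests on every pipeline run.

## Variance estimation and comparison

Weighted prevalences use Taylor linearization of the ratio estimator under
a with-replacement stratified cluster design: z-scores of PSU totals of
u<sub>j</sub> = w<sub>j</sub>(y<sub>j</sub> − p̂)/Ŵ within strata. Surveys
contribute their design (stratum, PSU); the EHR uses state as stratum and
county as cluster, so the geographic weights drive its variance. A stratum
with a single cluster contributes nothing (certainty-PSU convention).
CIs are p̂ ± 1.96·SE, truncated to [0, 100] after symmetric construction —
a small estimate can therefore print a CI like "0, 4.1". A with-replacement
cluster bootstrap (Rao–Wu rescaling) is implemented purely as a
cross-check; linearization is the production path. Replicate-weight
(BRR/jackknife) variance is out of scope.

Cross-source differences use t = (p₁ − p₂)/√(SE₁² + SE₂²) with a standard
normal reference by default (the cluster counts behind each SE are modest,
so this is mildly anti-conservative; a Satterthwaite-style t reference is
available via the `df` argument). Flags at α = 0.01: up/down arrows against
one comparator, doubled against both; machine output uses the tokens
`up, up2, down, down2, mixed`.

## The synthetic-data generator

The generator simulates a census of adults 50+ per state and derives all
three sources from it, so every downstream stage can be tested against
known truth.

* **Demography.** Four age bands (50–59, 60–69, 70–79, 80+ — coarse enough
  to keep county cells populated), sex, race/ethnicity, insurance,
  education and general health status with fixed categorical distributions;
  health status is worse among diabetics, giving the propensity and raking
  covariates real signal. Counties receive Dirichlet-distributed population
  shares and an optional age tilt that skews their age structure.
* **Disease truth.** Diabetes risk carries an age gradient (relative risks
  0.70/0.95/1.25/1.45 by band) and a county-level random effect (log scale,
  sd 0.15); the combined multiplier is normalized against the realized
  population so the expected state prevalence equals the configured value
  exactly. Comorbidity indicators are drawn conditional on diabetes;
  within-case "uncontrolled" rates are back-calculated so that control
  prevalence among the diagnosed hits its configured target while non-cases
  are always in range (so elevated biomarkers never contradict case
  status).
* **Biomarkers** are truncated normals conditional on status, truncated at
  the diagnostic and control cut points so that classification of a fully
  measured person is deterministic. Undiagnosed cases split into an
  A1c-detectable fraction (default 0.6) and a latent fraction visible only
  through FPG — the fraction the imputation stage exists to recover.
* **Observation processes.** EHR inclusion requires an office visit and a
  covered county (per-county coverage probabilities; half the counties
  uncovered by default). Diagnoses and prescriptions are recorded with
  sensitivity 0.95; A1c is measured for 52 % of diagnosed and 15 % of other
  patients, blood pressure for 96 %, and the lipid panel is coupled to A1c
  testing among the diagnosed (0.82 with / 0.07 without), reproducing the
  observed pattern that roughly 41 % of diagnosed patients carry all three
  measurements while the marginals are 52/96/46 %. The national survey is a
  stratified two-stage sample (states as strata, counties as
  with-replacement PSUs, default 8 × 150 per state) with FPG revealed for
  exactly half the respondents; the panel survey is a per-state SRS
  (defaults: 900 in CA, 700 in FL, 300 elsewhere — so two states clear the
  direct-estimation threshold and three go through division-synthetic
  estimation). The national sample size default (≈ 6 000) keeps at least
  ~30 elevated-FPG outcomes in the half-sample, the imputation model's
  minimum.
* **Determinism.** Every table is a pure function of (config, seed).

`simulate_survey_replicate` is a separate, lighter harness for calibration
studies of the variance machinery: equal-size with-replacement cluster
samples whose cluster prevalences are jittered symmetrically (uniform
± 0.03) around the truth, so the superpopulation prevalence is exact while
a genuine design effect is present.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: real ICD/NDC vocabularies (events carry a
condition-domain label); patients visiting multiple practices (no duplicate
records); survey nonresponse and recall bias (self-report sensitivity is
configurable but defaults to 1); within-person biomarker drift over time;
correlation between clinic coverage and unmeasured health determinants
beyond demographics; and finite-population corrections (all variance is
with-replacement). The acceptance studies show the machinery is correct
and well calibrated under these idealized conditions, not that any
particular real-world adjustment is unbiased.

## Study sizes

The bundled studies use: five states of 40 000 simulated residents for the
pipeline run; 100 replicates at 5 000 residents for the two-step weighting
study (EHR covering five young-skewed counties of ten, with a steepened
age gradient 0.5/0.8/1.4/1.8 so geographic coverage produces a strong,
purely demographic bias); 200 replicates of 25 × 4 × 50 cluster samples for
CI coverage and 400 replicate pairs for the type-I error of the
cross-source test; and 100 replicates of n = 2 000 with m = 5 completions
for imputation recovery under a known logistic law. These sizes make the
Monte-Carlo error small relative to the tolerances being checked while the
whole suite stays fast.

## Known limitations

* Synthetic state estimates inherit the assumption that the adjustment
  covariates capture the state-vs-nation difference; state effects beyond
  the covariates (which the generator deliberately includes via distinct
  configured prevalences) remain as bias, and CIs do not account for it.
* The EHR variance treats counties as few large clusters; with a handful of
  covered counties the SE itself is noisy.
* The normal reference for cross-source tests is mildly anti-conservative
  at small cluster counts.
* Trimming is ad hoc hygiene, not a calibrated variance-bias trade-off.
* Classification has no concept of conflicting records; the demographics
  table is authoritative for person attributes.
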