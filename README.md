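# statesurv

State-level surveillance of diabetes, its metabolic comorbidities
(hypertension, high cholesterol) and ABC control (hemoglobin **A**1c,
**B**lood pressure, **C**holesterol) from three very different kinds of
person-level data:

* a clustered **EHR extract** (six linked tables: visits, diagnoses, labs,
  prescriptions, providers, demographics) that covers only the counties
  where a clinic network operates and measures biomarkers non-randomly;
* a **national examination survey** with design weights, stratum/PSU
  identifiers, and fasting plasma glucose (FPG) measured on a random half
  of respondents;
* a **state-identified panel survey** of adults 50+, with biomarkers but no
  FPG.

The package is aimed at epidemiologists and survey statisticians who need
*state-level* prevalence and control estimates from sources that were never
designed for state-level estimation. It implements the full chain:
harmonization to a common dictionary, rule-based phenotyping, multiple
imputation of missing FPG evidence, calibration weighting, and design-based
estimation with cross-source significance testing. Because the real data
sources of this kind are restricted, a synthetic-data generator with known
ground truth is a first-class part of the package: every stage is testable
against the truth that generated its input.

## Methods at a glance

**Case definitions** (windows: case finding 2010-01-01..2013-12-31, control
2012-01-01..2013-12-31, both configurable):

* *diabetes*: diagnosed by self-report (surveys) or diagnosis/anti-diabetic
  prescription records (EHR); otherwise **undiagnosed** if any
  A1c ≥ 6.5 % or FPG ≥ 126 mg/dL; otherwise none.
* *hypertension*: ≥ 1 diagnosis, ≥ 2 elevated readings
  (SBP ≥ 140 or DBP ≥ 90 mmHg) on distinct dates, or a BP medication.
* *high cholesterol*: ≥ 1 diagnosis, lipid-lowering drug, or
  non-HDL-C = TC − HDL-C ≥ 130 mg/dL.
* *control* (diagnosed persons, tested-only denominators): A1c < 9 %,
  SBP < 140 and DBP < 90, non-HDL-C < 130.

**Weighting.** For a weight vector *w* and margin variables with control
totals *T<sub>c</sub>*, raking (iterative proportional fitting) repeats

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>i</sub> ← w<sub>i</sub> · T<sub>c(i)</sub> / Σ<sub>j∈c(i)</sub> w<sub>j</sub>*

over margins until every weighted cell total matches its target (relative
tolerance 1e−8). The EHR uses a two-step geographic scheme: (1) exact
post-stratification of each county to its census age × sex totals, so each
covered county carries weight proportional to its population; (2) raking of
the covered counties' age × sex totals to the state totals of the
office-visit population. The national survey is adjusted per target state by
an odds-of-membership propensity factor *p̂/(1 − p̂)* from a logistic model
against a state reference sample, followed by raking to state demographic
and health-status margins. The panel survey is used directly in states with
≥ 500 respondents and through its census division (same propensity + raking
machinery) elsewhere.

**Estimation.** Weighted prevalences carry Taylor-linearized standard
errors under a with-replacement stratified cluster design (surveys:
stratum/PSU; EHR: state/county, so the geographic weights enter the
variance). 95 % CIs are symmetric, truncated to [0, 100]. Sources are
compared with t = (p₁ − p₂)/√(SE₁² + SE₂²) at α = 0.01; report tables carry
↑/↓ arrows (doubled when a source differs from both others). Where FPG
evidence is imputed, estimates combine m = 10 completions by Rubin's rules.

## Worked example

```python
from statesurv import RunConfig, TruthConfig, run_pipeline

cfg = RunConfig()
cfg.truth = TruthConfig.small(2, 20000)          # 2 states, 20k residents each
cfg.truth.survey.national_psus_per_stratum = 10
cfg.truth.survey.national_persons_per_psu = 300
cfg.seed = 42; cfg.truth.seed = 42
res = run_pipeline(cfg)
print(res.report["prevalence"][["state", "measure", "ehr_pct", "ehr_ci",
                                "ehr_flag", "national_survey_pct",
                                "panel_survey_pct"]].to_string(index=False))
```

```
state              measure  ehr_pct     ehr_ci ehr_flag  national_survey_pct  panel_survey_pct
   AL   diagnosed_diabetes     21.4 20.9, 21.9     none                 20.9              28.7
   AL undiagnosed_diabetes      0.4   0.3, 0.4     down                  3.8               2.4
   CA   diagnosed_diabetes     16.9 16.3, 17.4     down                 20.6              17.5
   CA undiagnosed_diabetes      0.5   0.3, 0.7    down2                  3.8               5.2
```

The generating truth for undiagnosed diabetes was 3.5 % (AL) and 4.5 % (CA):
the surveys, with full biomarker panels plus FPG imputation, land near it,
while the EHR — which never measures FPG and orders A1c on a minority of
untested patients — sees almost none of it (0.4–0.5 %, flagged ↓/↓↓). The
measurement-completeness summary for the same run
(`res.completeness`) shows the non-random testing pattern among diagnosed
EHR patients: A1c 51.9 %, BP 97.2 %, cholesterol 46.6 %, all three 40.8 %.
The truth-recovery table (`res.recovery`) reports each estimate's error
against the realized population truth.

A command-line interface wraps the same pipeline:

```bash
statesurv simulate --seed 7 --out bundle/          # synthetic sources as CSV
statesurv run --config run.yaml --seed 7 --out out/
statesurv report --run-dir out/                    # markdown report tables
```

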