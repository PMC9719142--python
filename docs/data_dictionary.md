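# Harmonized data dictionary

All three sources are recoded to these tables (`HarmonizedSource`), written
and read as UTF-8 CSV with one header row.

## persons — one row per person

| column | type | notes |
|---|---|---|
| person_id | str | unique within source |
| source | str | `ehr`, `national_survey`, `panel_survey` |
| age | int | years |
| sex | str | `female`, `male` |
| race_eth | str | `white`, `black`, `hispanic`, `other`; missing for EHR |
| state | str | missing for the national survey (no state identifier) |
| county | str | EHR only |
| pregnant | bool | false where the source has no pregnancy item |
| office_visit_past_year | bool | EHR: derived from visit dates against the index date; surveys: questionnaire item |
| insurance | str | `private`, `medicare`, `medicaid`, `none`; missing for EHR |
| education | str | `lt_hs`, `hs`, `some_college`, `college`; missing for EHR |
| health_status | str | `excellent_vg`, `good`, `fair_poor`; missing for EHR |
| base_weight | float | design weight; 1.0 for EHR (census of its clinics) |
| stratum, psu | str | design identifiers; EHR uses state / county |

## labs — one row per analyte result

| column | type | notes |
|---|---|---|
| person_id | str | |
| analyte | str | `a1c` (%), `fpg` (mg/dL), `total_cholesterol` (mg/dL), `hdl_c` (mg/dL) |
| value | float | positive |
| date | date | survey measurements carry the examination date |

## vitals — one row per blood-pressure reading

| column | type | notes |
|---|---|---|
| person_id | str | |
| sbp, dbp | float | mmHg; sbp > dbp per reading |
| date | date | |

## events — one row per diagnosis / prescription / self-report

| column | type | notes |
|---|---|---|
| person_id | str | |
| kind | str | `diagnosis`, `prescription`, `self_report` |
| domain | str | `diabetes`, `hypertension`, `cholesterol` |
| date | date | |
| gestational | bool | diabetes self-reports only; gestational-only history |

## Margin tables

* `county_age_sex.csv`: state, county, age_band, sex, target — census
  age × sex counts per county (post-stratification targets).
* `state_age_sex_officevisit.csv`: state, age_band, sex, target — state
  counts restricted to persons with an office visit in the past year (the
  EHR step-2 raking target).
* `state_margins.csv`: state, variable, cell, target — marginal counts of
  the adjustment variables (age_band, sex, race_eth, insurance, education,
  health_status) for survey calibration.

Age bands are `50-59`, `60-69`, `70-79`, `80+`.
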