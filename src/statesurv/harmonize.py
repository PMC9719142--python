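"""Harmonize the three raw sources into a common person-level dictionary.

Every source ends up as a :class:`HarmonizedSource`: one demographics/design
row per person (``persons``) plus long-format clinical history tables
(``labs``, ``vitals``, ``events``). Column names, analyte labels and event
domains are identical across sources, so case definitions and estimation
never branch on provenance except where the method genuinely differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EDUCATION_LEVELS, HEALTH_LEVELS, INSURANCE_LEVELS, RACE_LEVELS, SEXES

log = logging.getLogger(__name__)

ANALYTES = ("a1c", "fpg", "total_cholesterol", "hdl_c")
EVENT_KINDS = ("diagnosis", "prescription", "self_report")
EVENT_DOMAINS = ("diabetes", "hypertension", "cholesterol")

PERSON_COLUMNS = [
    "person_id", "source", "age", "sex", "race_eth", "state", "county",
    "pregnant", "office_visit_past_year", "insurance", "education",
    "health_status", "base_weight", "stratum", "psu",
]

# default examination date assigned to survey measurements; inside both the
# control and case-finding windows so single-occasion panels count everywhere
DEFAULT_EXAM_DATE = date(2012, 7, 1)


@dataclass
class HarmonizedSource:
    """One source recoded to the common dictionary."""

    source: str
    persons: pd.DataFrame
    labs: pd.DataFrame      # person_id, analyte, value, date
    vitals: pd.DataFrame    # person_id, sbp, dbp, date
    events: pd.DataFrame    # person_id, kind, domain, date, gestational
    orphan_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.persons["person_id"].duplicated().any():
            raise ValueError(f"{self.source}: duplicate person_id in persons")
        if self.source != "ehr" and (self.persons["base_weight"] <= 0).any():
            raise ValueError(f"{self.source}: nonpositive base_weight")
        bad = set(self.labs["analyte"]) - set(ANALYTES)
        if bad:
            raise ValueError(f"{self.source}: unknown analytes {sorted(bad)}")
        if len(self.labs) and (self.labs["value"] <= 0).any():
            raise ValueError(f"{self.source}: nonpositive lab values")
        if len(self.vitals) and (self.vitals["sbp"] <= self.vitals["dbp"]).any():
            raise ValueError(f"{self.source}: systolic must exceed diastolic")


def _empty_labs() -> pd.DataFrame:
    return pd.DataFrame({"person_id": pd.Series(dtype=object),
                         "analyte": pd.Series(dtype=object),
                         "value": pd.Series(dtype=float),
                         "date": pd.Series(dtype="datetime64[ns]")})


def _empty_vitals() -> pd.DataFrame:
    return pd.DataFrame({"person_id": pd.Series(dtype=object),
                         "sbp": pd.Series(dtype=float), "dbp": pd.Series(dtype=float),
                         "date": pd.Series(dtype="datetime64[ns]")})


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({"person_id": pd.Series(dtype=object),
                         "kind": pd.Series(dtype=object),
                         "domain": pd.Series(dtype=object),
                         "date": pd.Series(dtype="datetime64[ns]"),
                         "gestational": pd.Series(dtype=bool)})


def merge_ehr_tables(tables: dict[str, pd.DataFrame],
                     index_date: date = date(2013, 12, 31)) -> HarmonizedSource:
    """Merge the six-table EHR extract into one record per person.

    The demographics table is authoritative: rows in any other table whose
    person ID it does not contain are orphans — logged, dropped, and counted
    in ``orphan_counts``. ``office_visit_past_year`` is true when any visit
    falls within the 12 months ending at ``index_date``. Duplicate same-day
    identical lab rows are dropped.
    """
    required = {"demographics", "visits", "diagnoses", "labs", "prescriptions", "providers"}
    missing = required - set(tables)
    if missing:
        raise ValueError(f"missing EHR tables: {sorted(missing)}")
    demo = tables["demographics"].drop_duplicates("person_id").copy()
    known = set(demo["person_id"])
    orphans: dict[str, int] = {}

    def _keep(name: str) -> pd.DataFrame:
        df = tables[name]
        ok = df["person_id"].isin(known)
        orphans[name] = int((~ok).sum())
        if orphans[name]:
            log.warning("ehr %s: dropped %d orphan rows", name, orphans[name])
        return df[ok].copy()

    visits = _keep("visits")
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    window_start = pd.Timestamp(index_date - timedelta(days=365))
    recent = visits[(visits["visit_date"] > window_start)
                    & (visits["visit_date"] <= pd.Timestamp(index_date))]
    has_recent = set(recent["person_id"])

    labs = _keep("labs")
    if len(labs):
        labs["date"] = pd.to_datetime(labs["date"])
        labs = (labs[["person_id", "analyte", "value", "date"]]
                .drop_duplicates())
    else:
        labs = _empty_labs()

    vit = visits[visits[["sbp", "dbp"]].notna().all(axis=1)]
    vitals = (vit.rename(columns={"visit_date": "date"})
              [["person_id", "sbp", "dbp", "date"]].reset_index(drop=True)
              if len(vit) else _empty_vitals())

    ev_parts = []
    for name, kind in (("diagnoses", "diagnosis"), ("prescriptions", "prescription")):
        df = _keep(name)
        if not len(df):
            continue
        bad = set(df["domain"]) - set(EVENT_DOMAINS)
        if bad:
            raise ValueError(f"ehr {name}: unknown domain values {sorted(bad)}")
        ev_parts.append(pd.DataFrame({
            "person_id": df["person_id"].to_numpy(), "kind": kind,
            "domain": df["domain"].to_numpy(),
            "date": pd.to_datetime(df["date"]).to_numpy(),
            "gestational": False,
        }))
    events = pd.concat(ev_parts, ignore_index=True) if ev_parts else _empty_events()

    persons = pd.DataFrame({
        "person_id": demo["person_id"].to_numpy(),
        "source": "ehr",
        "age": demo["age"].to_numpy(),
        "sex": demo["sex"].to_numpy(),
        "race_eth": np.nan,
        "state": demo["state"].to_numpy(),
        "county": demo["county"].to_numpy(),
        "pregnant": False,
        "office_visit_past_year": demo["person_id"].isin(has_recent).to_numpy(),
        "insurance": np.nan, "education": np.nan, "health_status": np.nan,
        "base_weight": 1.0,
        "stratum": demo["state"].to_numpy(),
        "psu": demo["county"].to_numpy(),
    })[PERSON_COLUMNS]
    _check_categories(persons, "sex", SEXES)
    out = HarmonizedSource("ehr", persons, labs, vitals, events, orphans)
    out.validate()
    return out


def _check_categories(df: pd.DataFrame, column: str, allowed) -> None:
    vals = df[column].dropna()
    bad = set(vals) - set(allowed)
    if bad:
        raise ValueError(f"unknown category codes in column '{column}': {sorted(bad)}")


_SURVEY_CATEGORY_CHECKS = {
    "sex": SEXES, "race_eth": RACE_LEVELS, "insurance": INSURANCE_LEVELS,
    "education": EDUCATION_LEVELS, "health_status": HEALTH_LEVELS,
}


def harmonize_survey(raw: pd.DataFrame, source: str,
                     exam_date: date = DEFAULT_EXAM_DATE) -> HarmonizedSource:
    """Recode a survey file to the common dictionary.

    Biomarkers become dated lab/vital rows at the examination date;
    self-reported diagnoses become ``self_report`` events. Missing fasting
    glucose stays missing — imputation is a separate, explicit stage.
    """
    if source not in ("national_survey", "panel_survey"):
        raise ValueError(f"unknown survey source tag: {source}")
    required = {"person_id", "age", "sex", "base_weight", "stratum", "psu"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{source}: missing required columns {sorted(missing)}")
    for col, allowed in _SURVEY_CATEGORY_CHECKS.items():
        if col in raw.columns:
            _check_categories(raw, col, allowed)

    n = len(raw)
    persons = pd.DataFrame({
        "person_id": raw["person_id"].to_numpy(),
        "source": source,
        "age": raw["age"].to_numpy(),
        "sex": raw["sex"].to_numpy(),
        "race_eth": raw.get("race_eth", pd.Series([np.nan] * n)).to_numpy(),
        "state": raw.get("state", pd.Series([np.nan] * n)).to_numpy(),
        "county": np.nan,
        "pregnant": raw.get("pregnant", pd.Series([False] * n)).to_numpy(),
        "office_visit_past_year": raw.get("office_visit",
                                          pd.Series([True] * n)).to_numpy(),
        "insurance": raw.get("insurance", pd.Series([np.nan] * n)).to_numpy(),
        "education": raw.get("education", pd.Series([np.nan] * n)).to_numpy(),
        "health_status": raw.get("health_status", pd.Series([np.nan] * n)).to_numpy(),
        "base_weight": raw["base_weight"].to_numpy(dtype=float),
        "stratum": raw["stratum"].to_numpy(),
        "psu": raw["psu"].to_numpy(),
    })[PERSON_COLUMNS]

    ts = pd.Timestamp(exam_date)
    lab_parts = []
    for col, analyte in (("a1c", "a1c"), ("fpg", "fpg"),
                         ("tc", "total_cholesterol"), ("hdl", "hdl_c")):
        if col not in raw.columns:
            continue
        present = raw[col].notna()
        lab_parts.append(pd.DataFrame({
            "person_id": raw.loc[present, "person_id"].to_numpy(),
            "analyte": analyte,
            "value": raw.loc[present, col].to_numpy(dtype=float),
            "date": ts,
        }))
    labs = pd.concat(lab_parts, ignore_index=True) if lab_parts else _empty_labs()

    vital_parts = []
    for i in (1, 2):
        if f"sbp{i}" in raw.columns:
            ok = raw[[f"sbp{i}", f"dbp{i}"]].notna().all(axis=1)
            vital_parts.append(pd.DataFrame({
                "person_id": raw.loc[ok, "person_id"].to_numpy(),
                "sbp": raw.loc[ok, f"sbp{i}"].to_numpy(dtype=float),
                "dbp": raw.loc[ok, f"dbp{i}"].to_numpy(dtype=float),
                "date": ts,
            }))
    vitals = pd.concat(vital_parts, ignore_index=True) if vital_parts else _empty_vitals()

    ev_parts = []
    for col, domain in (("self_report_diabetes", "diabetes"),
                        ("self_report_htn", "hypertension"),
                        ("self_report_chol", "cholesterol")):
        if col not in raw.columns:
            continue
        flagged = raw[raw[col].astype(bool)]
        gest = (flagged.get("gestational_only", pd.Series(False, index=flagged.index))
                .astype(bool).to_numpy() if domain == "diabetes"
                else np.zeros(len(flagged), dtype=bool))
        ev_parts.append(pd.DataFrame({
            "person_id": flagged["person_id"].to_numpy(),
            "kind": "self_report", "domain": domain, "date": ts,
            "gestational": gest,
        }))
    events = pd.concat(ev_parts, ignore_index=True) if ev_parts else _empty_events()

    out = HarmonizedSource(source, persons, labs, vitals, events, {})
    out.validate()
    return out


def write_harmonized(src: HarmonizedSource, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    src.persons.to_csv(out / f"{src.source}_persons.csv", index=False)
    src.labs.to_csv(out / f"{src.source}_labs.csv", index=False)
    src.vitals.to_csv(out / f"{src.source}_vitals.csv", index=False)
    src.events.to_csv(out / f"{src.source}_events.csv", index=False)


def read_harmonized(source: str, indir: str | Path) -> HarmonizedSource:
    ind = Path(indir)
    persons = pd.read_csv(ind / f"{source}_persons.csv",
                          dtype={"stratum": object, "psu": object})
    for col in ("pregnant", "office_visit_past_year"):
        persons[col] = persons[col].astype(bool)
    labs = pd.read_csv(ind / f"{source}_labs.csv", parse_dates=["date"])
    vitals = pd.read_csv(ind / f"{source}_vitals.csv", parse_dates=["date"])
    events = pd.read_csv(ind / f"{source}_events.csv", parse_dates=["date"])
    if "gestational" in events.columns:
        events["gestational"] = events["gestational"].astype(bool)
    out = HarmonizedSource(source, persons, labs, vitals, events, {})
    out.validate()
    return out
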