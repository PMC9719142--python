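"""Harmonized case definitions for diabetes, hypertension, high cholesterol
and ABC control.

Diagnostic cut points are inclusive (A1c >= 6.5 %, FPG >= 126 mg/dL,
SBP >= 140 / DBP >= 90 mmHg, non-HDL-C >= 130 mg/dL); control targets are
exclusive (A1c < 9 %, SBP < 140 and DBP < 90, non-HDL-C < 130). Diabetes is
split into diagnosed / undiagnosed / none; hypertension and high cholesterol
are single flags with no diagnosed-undiagnosed distinction. Control is
assessed only in the diagnosed population, and each component is ``untested``
when no qualifying measurement exists in the control window — estimates over
control restrict their denominators to tested persons.

Classification is a pure function of (record, history, windows, cut points):
event and lab order never matters, and adding an elevated result can only
move a person toward case status, never away from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CutPoints, RuleWindows
from .harmonize import HarmonizedSource

DIABETES_LEVELS = ("diagnosed", "undiagnosed", "none")
CONTROL_LEVELS = ("in_control", "not_in_control", "untested")


def apply_eligibility(record: Mapping, min_age: int = 50) -> bool:
    """Analysis-population rule: age at or above ``min_age`` (inclusive),
    an office visit in the past year, and not pregnant. A missing age is
    ineligible."""
    age = record.get("age")
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return False
    return bool(age >= min_age and record.get("office_visit_past_year", False)
                and not record.get("pregnant", False))


@dataclass
class ClassifiedPopulation:
    """Per-person disease status table plus bookkeeping counts."""

    statuses: pd.DataFrame
    missing_age_count: int = 0
    tc_without_hdl_count: int = 0
    counts: dict = field(default_factory=dict)


def _window_mask(dates: pd.Series, start, end) -> pd.Series:
    return (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))


def _latest_mean(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Per person: mean of the value columns over the most recent date
    (same-day repeats are one measurement occasion)."""
    if not len(df):
        return pd.DataFrame(columns=["person_id", *value_cols])
    last = df.groupby("person_id")["date"].transform("max")
    recent = df[df["date"] == last]
    return recent.groupby("person_id", as_index=False)[value_cols].mean()


def _nonhdl_pairs(labs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join total cholesterol to same-date HDL and compute non-HDL-C.
    Returns (pairs with person_id/date/nonhdl, count of TC rows without a
    same-date HDL partner)."""
    tc = labs[labs["analyte"] == "total_cholesterol"]
    hdl = labs[labs["analyte"] == "hdl_c"]
    if not len(tc):
        return pd.DataFrame(columns=["person_id", "date", "nonhdl"]), 0
    pairs = tc.merge(hdl, on=["person_id", "date"], suffixes=("_tc", "_hdl"),
                     how="left")
    unmatched = int(pairs["value_hdl"].isna().sum())
    pairs = pairs.dropna(subset=["value_hdl"])
    out = pd.DataFrame({
        "person_id": pairs["person_id"].to_numpy(),
        "date": pairs["date"].to_numpy(),
        "nonhdl": (pairs["value_tc"] - pairs["value_hdl"]).to_numpy(),
    })
    return out, unmatched


def classify_population(src: HarmonizedSource,
                        windows: RuleWindows | None = None,
                        cuts: CutPoints = CutPoints(),
                        min_age: int = 50,
                        ehr_abc_filter: bool = True) -> ClassifiedPopulation:
    """Classify every person in a harmonized source.

    Returns one row per person with eligibility, the three-way diabetes
    category, comorbidity flags, and the three control components (control
    assessed for the diagnosed only; others carry missing values).

    For the EHR source, persons without at least one ABC result (A1c, blood
    pressure, or a full cholesterol panel) in the control window are not
    assigned a disease status: ``eligible`` is false for them when
    ``ehr_abc_filter`` is set, since the record-based method cannot see them.
    """
    windows = windows or RuleWindows()
    windows.validate()
    persons = src.persons
    pid = persons["person_id"]
    n = len(persons)

    age = pd.to_numeric(persons["age"], errors="coerce")
    missing_age = int(age.isna().sum())
    eligible = (age.ge(min_age).fillna(False)
                & persons["office_visit_past_year"].astype(bool)
                & ~persons["pregnant"].astype(bool))

    labs = src.labs[_window_mask(src.labs["date"], windows.case_start, windows.case_end)] \
        if len(src.labs) else src.labs
    vitals = src.vitals[_window_mask(src.vitals["date"], windows.case_start, windows.case_end)] \
        if len(src.vitals) else src.vitals
    events = src.events[_window_mask(src.events["date"], windows.case_start, windows.case_end)] \
        if len(src.events) else src.events

    ctrl_labs = labs[_window_mask(labs["date"], windows.control_start, windows.control_end)] \
        if len(labs) else labs
    ctrl_vitals = vitals[_window_mask(vitals["date"], windows.control_start,
                                      windows.control_end)] if len(vitals) else vitals

    # --- EHR analysis-population gate: >= 1 ABC result in the control window
    ctrl_pairs, _ = _nonhdl_pairs(ctrl_labs)
    has_a1c_ctrl = set(ctrl_labs.loc[ctrl_labs["analyte"] == "a1c", "person_id"])
    has_bp_ctrl = set(ctrl_vitals["person_id"]) if len(ctrl_vitals) else set()
    has_chol_ctrl = set(ctrl_pairs["person_id"])
    has_abc = pid.isin(has_a1c_ctrl | has_bp_ctrl | has_chol_ctrl)
    if src.source == "ehr" and ehr_abc_filter:
        eligible = eligible & has_abc

    # --- diabetes ------------------------------------------------------
    if src.source == "ehr":
        dx = events[(events["domain"] == "diabetes")
                    & events["kind"].isin(["diagnosis", "prescription"])]
    else:
        dx = events[(events["domain"] == "diabetes")
                    & (events["kind"] == "self_report")
                    & ~events["gestational"].astype(bool)]
    diagnosed = pid.isin(set(dx["person_id"]))

    a1c_case = labs[(labs["analyte"] == "a1c") & (labs["value"] >= cuts.a1c_diabetes)]
    fpg_case = labs[(labs["analyte"] == "fpg") & (labs["value"] >= cuts.fpg_diabetes)]
    biomarker_pos = pid.isin(set(a1c_case["person_id"]) | set(fpg_case["person_id"]))
    diabetes = np.where(diagnosed, "diagnosed",
                        np.where(biomarker_pos, "undiagnosed", "none"))

    # --- hypertension --------------------------------------------------
    htn_events = events[events["domain"] == "hypertension"]
    has_htn_event = pid.isin(set(htn_events["person_id"]))
    if len(vitals):
        elev = vitals[(vitals["sbp"] >= cuts.sbp_elevated)
                      | (vitals["dbp"] >= cuts.dbp_elevated)]
        # two or more elevated readings on distinct dates
        n_dates = elev.groupby("person_id")["date"].nunique()
        two_elev = pid.isin(set(n_dates[n_dates >= 2].index))
    else:
        two_elev = pd.Series(False, index=persons.index)
    hypertension = has_htn_event | two_elev

    # --- high cholesterol ----------------------------------------------
    chol_events = events[events["domain"] == "cholesterol"]
    has_chol_event = pid.isin(set(chol_events["person_id"]))
    pairs, tc_unmatched = _nonhdl_pairs(labs)
    high_pairs = pairs[pairs["nonhdl"] >= cuts.nonhdl_high]
    high_cholesterol = has_chol_event | pid.isin(set(high_pairs["person_id"]))

    # --- ABC control among the diagnosed -------------------------------
    a1c_recent = _latest_mean(ctrl_labs[ctrl_labs["analyte"] == "a1c"], ["value"]) \
        .set_index("person_id")["value"]
    bp_recent = _latest_mean(ctrl_vitals, ["sbp", "dbp"]).set_index("person_id") \
        if len(ctrl_vitals) else pd.DataFrame(columns=["sbp", "dbp"])
    chol_recent = _latest_mean(ctrl_pairs, ["nonhdl"]).set_index("person_id")["nonhdl"] \
        if len(ctrl_pairs) else pd.Series(dtype=float)

    def _control(values: pd.Series, ok_mask_fn) -> np.ndarray:
        vals = pid.map(values)
        out = np.where(vals.isna(), "untested",
                       np.where(ok_mask_fn(vals), "in_control", "not_in_control"))
        return out

    a1c_control = _control(a1c_recent, lambda v: v < cuts.a1c_poor_control)
    if len(bp_recent):
        sbp = pid.map(bp_recent["sbp"])
        dbp = pid.map(bp_recent["dbp"])
        bp_control = np.where(sbp.isna(), "untested",
                              np.where((sbp < cuts.sbp_elevated)
                                       & (dbp < cuts.dbp_elevated),
                                       "in_control", "not_in_control"))
    else:
        bp_control = np.full(n, "untested", dtype=object)
    chol_control = _control(chol_recent, lambda v: v < cuts.nonhdl_high)

    is_diag = diabetes == "diagnosed"
    statuses = pd.DataFrame({
        "person_id": pid.to_numpy(),
        "source": src.source,
        "eligible": eligible.to_numpy(),
        "has_abc": has_abc.to_numpy(),
        "diabetes": diabetes,
        "hypertension": hypertension.to_numpy(),
        "high_cholesterol": high_cholesterol.to_numpy(),
        "a1c_control": np.where(is_diag, a1c_control, None),
        "bp_control": np.where(is_diag, bp_control, None),
        "chol_control": np.where(is_diag, chol_control, None),
    })
    counts = {"missing_age": missing_age, "tc_without_hdl": tc_unmatched,
              "n_eligible": int(eligible.sum())}
    return ClassifiedPopulation(statuses, missing_age, tc_unmatched, counts)


# ---------------------------------------------------------------------------
# Per-person wrappers: build a one-person source and reuse the population
# classifier, so fixture-level checks exercise exactly the production path.
# ---------------------------------------------------------------------------

def _one_person_source(source: str, labs=None, vitals=None, events=None,
                       record: Mapping | None = None) -> HarmonizedSource:
    from .harmonize import _empty_events, _empty_labs, _empty_vitals

    rec = {"person_id": "p0", "source": source, "age": 60, "sex": "female",
           "race_eth": None, "state": "XX", "county": None, "pregnant": False,
           "office_visit_past_year": True, "insurance": None, "education": None,
           "health_status": None, "base_weight": 1.0, "stratum": "s", "psu": "p"}
    if record:
        rec.update(record)
    persons = pd.DataFrame([rec])

    def _frame(rows, maker, cols):
        if rows is None or not len(rows):
            return maker()
        df = pd.DataFrame(rows)
        df["person_id"] = df.get("person_id", "p0")
        df["date"] = pd.to_datetime(df["date"])
        if "gestational" in cols and "gestational" not in df.columns:
            df["gestational"] = False
        return df[cols]

    return HarmonizedSource(
        source, persons,
        _frame(labs, _empty_labs, ["person_id", "analyte", "value", "date"]),
        _frame(vitals, _empty_vitals, ["person_id", "sbp", "dbp", "date"]),
        _frame(events, _empty_events,
               ["person_id", "kind", "domain", "date", "gestational"]),
    )


def classify_diabetes(source: str, labs=None, events=None,
                      windows: RuleWindows | None = None,
                      cuts: CutPoints = CutPoints()) -> str:
    """Three-way diabetes category for a single person's history."""
    src = _one_person_source(source, labs=labs, events=events)
    cp = classify_population(src, windows, cuts, ehr_abc_filter=False)
    return cp.statuses["diabetes"].iloc[0]


def classify_hypertension(vitals=None, events=None,
                          windows: RuleWindows | None = None,
                          cuts: CutPoints = CutPoints()) -> bool:
    src = _one_person_source("ehr", vitals=vitals, events=events)
    cp = classify_population(src, windows, cuts, ehr_abc_filter=False)
    return bool(cp.statuses["hypertension"].iloc[0])


def classify_high_cholesterol(labs=None, events=None,
                              windows: RuleWindows | None = None,
                              cuts: CutPoints = CutPoints()) -> bool:
    src = _one_person_source("ehr", labs=labs, events=events)
    cp = classify_population(src, windows, cuts, ehr_abc_filter=False)
    return bool(cp.statuses["high_cholesterol"].iloc[0])


def assess_control(labs=None, vitals=None,
                   windows: RuleWindows | None = None,
                   cuts: CutPoints = CutPoints()) -> tuple[str, str, str]:
    """(A1c, BP, cholesterol) control for a single diagnosed person."""
    events = [{"kind": "diagnosis", "domain": "diabetes", "date": "2012-06-01"}]
    src = _one_person_source("ehr", labs=labs, vitals=vitals, events=events)
    cp = classify_population(src, windows, cuts, ehr_abc_filter=False)
    row = cp.statuses.iloc[0]
    return row["a1c_control"], row["bp_control"], row["chol_control"]
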