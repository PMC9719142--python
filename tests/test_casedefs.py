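"""Case-definition rules: boundaries, purity, and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from statesurv import (apply_eligibility, assess_control, classify_diabetes,
                       classify_high_cholesterol, classify_hypertension,
                       classify_population, merge_ehr_tables)
from statesurv.casedefs import _one_person_source

D = "2012-06-15"  # inside both the control and case-finding windows


def lab(analyte, value, date=D):
    return {"analyte": analyte, "value": value, "date": date}


def ev(kind, domain, date=D, **kw):
    return {"kind": kind, "domain": domain, "date": date, **kw}


class TestEligibility:
    @pytest.mark.parametrize("record,expected", [
        ({"age": 50, "office_visit_past_year": True, "pregnant": False}, True),
        ({"age": 49, "office_visit_past_year": True, "pregnant": False}, False),
        ({"age": 62, "office_visit_past_year": True, "pregnant": True}, False),
        ({"age": 75, "office_visit_past_year": False, "pregnant": False}, False),
        ({"age": np.nan, "office_visit_past_year": True, "pregnant": False}, False),
    ])
    def test_age_visit_pregnancy_rule(self, record, expected):
        assert apply_eligibility(record) is expected

    def test_adult_mode_lowers_age_floor(self):
        rec = {"age": 30, "office_visit_past_year": True, "pregnant": False}
        assert not apply_eligibility(rec)
        assert apply_eligibility(rec, min_age=18)

    def test_missing_age_counted(self):
        src = _one_person_source("ehr", record={"age": np.nan})
        cp = classify_population(src)
        assert cp.missing_age_count == 1
        assert not cp.statuses["eligible"].iloc[0]


class TestDiabetes:
    @pytest.mark.parametrize("labs,events,expected", [
        ([lab("a1c", 5.8)], [ev("self_report", "diabetes")], "diagnosed"),
        ([lab("a1c", 6.5)], [], "undiagnosed"),
        ([lab("a1c", 6.4), lab("fpg", 125)], [], "none"),
        ([lab("fpg", 126)], [], "undiagnosed"),
        ([lab("fpg", 125.9)], [], "none"),
    ])
    def test_survey_boundaries(self, labs, events, expected):
        assert classify_diabetes("panel_survey", labs, events) == expected

    def test_ehr_diagnosis_or_prescription_event(self):
        for kind in ("diagnosis", "prescription"):
            assert classify_diabetes("ehr", [lab("a1c", 5.6)],
                                     [ev(kind, "diabetes")]) == "diagnosed"

    def test_gestational_self_report_excluded(self):
        events = [ev("self_report", "diabetes", gestational=True)]
        assert classify_diabetes("panel_survey", [lab("a1c", 5.8)], events) == "none"

    def test_self_report_ignored_for_ehr(self):
        assert classify_diabetes("ehr", [], [ev("self_report", "diabetes")]) == "none"

    def test_lab_outside_case_window_cannot_trigger(self):
        assert classify_diabetes("ehr", [lab("a1c", 7.5, "2009-06-01")], []) == "none"

    def test_ehr_without_abc_result_not_assigned_status(self):
        # diagnosis event but no ABC result in the control window
        src = _one_person_source("ehr", events=[ev("diagnosis", "diabetes")])
        cp = classify_population(src, ehr_abc_filter=True)
        assert not cp.statuses["eligible"].iloc[0]
        src2 = _one_person_source("ehr", events=[ev("diagnosis", "diabetes")],
                                  labs=[lab("a1c", 7.0)])
        cp2 = classify_population(src2, ehr_abc_filter=True)
        assert cp2.statuses["eligible"].iloc[0]


def bp(sbp, dbp, date=D):
    return {"sbp": sbp, "dbp": dbp, "date": date}


class TestHypertension:
    def test_single_elevated_reading_insufficient(self):
        assert not classify_hypertension(vitals=[bp(150, 80)])

    def test_two_readings_each_elevated_on_one_component(self):
        assert classify_hypertension(vitals=[bp(138, 92, "2012-01-10"),
                                             bp(141, 85, "2012-05-10")])

    def test_boundary_values_inclusive(self):
        assert classify_hypertension(vitals=[bp(140, 70, "2012-01-10"),
                                             bp(125, 90, "2012-05-10")])
        assert not classify_hypertension(vitals=[bp(139, 89, "2012-01-10"),
                                                 bp(139, 89, "2012-05-10")])

    def test_two_elevated_same_day_do_not_count_twice(self):
        assert not classify_hypertension(vitals=[bp(150, 80), bp(155, 82)])

    def test_medication_or_diagnosis_alone_suffices(self):
        assert classify_hypertension(events=[ev("prescription", "hypertension")])
        assert classify_hypertension(events=[ev("diagnosis", "hypertension")])


class TestHighCholesterol:
    def test_nonhdl_boundary(self):
        assert classify_high_cholesterol(labs=[lab("total_cholesterol", 200),
                                               lab("hdl_c", 60)])      # 140
        assert not classify_high_cholesterol(labs=[lab("total_cholesterol", 180),
                                                   lab("hdl_c", 55)])  # 125
        assert classify_high_cholesterol(labs=[lab("total_cholesterol", 190),
                                               lab("hdl_c", 60)])      # exactly 130

    def test_statin_prescription_alone_suffices(self):
        assert classify_high_cholesterol(events=[ev("prescription", "cholesterol")])

    def test_tc_without_same_date_hdl_contributes_nothing(self):
        src = _one_person_source("ehr", labs=[lab("total_cholesterol", 300)])
        cp = classify_population(src, ehr_abc_filter=False)
        assert not cp.statuses["high_cholesterol"].iloc[0]
        assert cp.tc_without_hdl_count == 1


class TestControl:
    def test_a1c_control_boundary_exclusive(self):
        assert assess_control(labs=[lab("a1c", 8.9)])[0] == "in_control"
        assert assess_control(labs=[lab("a1c", 9.0)])[0] == "not_in_control"

    def test_bp_control_requires_both_components(self):
        assert assess_control(vitals=[bp(139, 89)])[1] == "in_control"
        assert assess_control(vitals=[bp(139, 90)])[1] == "not_in_control"
        assert assess_control(vitals=[bp(140, 89)])[1] == "not_in_control"

    def test_chol_control_boundary(self):
        good = [lab("total_cholesterol", 180), lab("hdl_c", 55)]
        assert assess_control(labs=good)[2] == "in_control"
        bad = [lab("total_cholesterol", 190), lab("hdl_c", 60)]
        assert assess_control(labs=bad)[2] == "not_in_control"

    def test_untested_when_no_panel_in_control_window(self):
        assert assess_control()[2] == "untested"
        # an old panel outside the control window does not count
        old = [lab("total_cholesterol", 300, "2011-06-01"),
               lab("hdl_c", 40, "2011-06-01")]
        assert assess_control(labs=old)[2] == "untested"

    def test_most_recent_value_decides(self):
        labs = [lab("a1c", 9.5, "2012-03-01"), lab("a1c", 8.0, "2013-09-01")]
        assert assess_control(labs=labs)[0] == "in_control"
        assert assess_control(labs=list(reversed(labs)))[0] == "in_control"


class TestPopulationProperties:
    def test_event_order_never_matters(self, small_bundle):
        src = merge_ehr_tables(small_bundle.ehr_tables)
        shuffled = merge_ehr_tables({
            k: v.sample(frac=1.0, random_state=3).reset_index(drop=True)
            for k, v in small_bundle.ehr_tables.items()})
        a = classify_population(src).statuses.sort_values("person_id")
        b = classify_population(shuffled).statuses.sort_values("person_id")
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_adding_elevated_lab_never_removes_case(self):
        base_labs = [lab("a1c", 6.0)]
        before = classify_diabetes("ehr", base_labs, [])
        after = classify_diabetes("ehr", base_labs + [lab("fpg", 140)], [])
        order = {"none": 0, "undiagnosed": 1, "diagnosed": 2}
        assert order[after] >= order[before]
        assert classify_high_cholesterol(
            labs=[lab("total_cholesterol", 180), lab("hdl_c", 55),
                  lab("total_cholesterol", 250, "2013-01-05"),
                  lab("hdl_c", 40, "2013-01-05")])

    def test_partition_of_eligible_population(self, small_bundle):
        src = merge_ehr_tables(small_bundle.ehr_tables)
        st = classify_population(src).statuses
        el = st[st["eligible"]]
        assert el["diabetes"].isin(["diagnosed", "undiagnosed", "none"]).all()

    def test_perfect_recording_reproduces_truth_exactly(self, exact_bundle):
        src = merge_ehr_tables(exact_bundle.ehr_tables)
        st = classify_population(src).statuses.set_index("person_id")
        census = exact_bundle.census.set_index("person_id")
        joined = st.join(census, rsuffix="_true")
        el = joined[joined["eligible"]]
        assert (el["diabetes"] == el["diabetes_true"]).all()
        assert (el["hypertension"] == el["htn"]).all()
        assert (el["high_cholesterol"] == el["hichol"]).all()
        diag = el[el["diabetes"] == "diagnosed"]
        assert ((diag["a1c_control"] == "in_control") == ~diag["a1c_poor"]).all()
        assert ((diag["bp_control"] == "in_control") == ~diag["bp_elev"]).all()
        assert ((diag["chol_control"] == "in_control") == ~diag["chol_elev"]).all()
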