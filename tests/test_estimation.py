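"""Design-based estimation: linearized SEs, comparisons, report structure."""

import numpy as np
import pandas as pd
import pytest

from statesurv import build_report, compare_sources, weighted_prevalence
from statesurv.estimation import bootstrap_se
from statesurv.synthetic import simulate_survey_replicate


def linearized_se_oracle(df):
    """Hand-coded with-replacement linearization for a weighted proportion,
    written against the textbook formula rather than the production path."""
    w, y = df["weight"].to_numpy(float), df["y"].to_numpy(float)
    n_hat = w.sum()
    p = (w * y).sum() / n_hat
    var = 0.0
    for _, s in df.groupby("stratum"):
        totals = [((g["weight"] * (g["y"] - p)).sum() / n_hat)
                  for _, g in s.groupby("psu")]
        n_h = len(totals)
        if n_h < 2:
            continue
        zbar = np.mean(totals)
        var += n_h / (n_h - 1) * sum((z - zbar) ** 2 for z in totals)
    return np.sqrt(var) * 100


def _toy(y, weight, stratum, psu):
    return pd.DataFrame({"y": y, "weight": weight, "stratum": stratum, "psu": psu})


class TestWeightedPrevalence:
    def test_equal_weights_reduce_to_plain_proportion(self):
        df = _toy([1] * 20 + [0] * 80, 1.0, "s", [f"p{i}" for i in range(100)])
        est = weighted_prevalence(df)
        assert est.point == pytest.approx(20.0)

    def test_degenerate_all_positive(self):
        df = _toy([1] * 10, 2.0, "s", [f"p{i}" for i in range(10)])
        est = weighted_prevalence(df)
        assert est.point == 100.0
        assert est.se == 0.0
        assert (est.ci_low, est.ci_high) == (100.0, 100.0)

    def test_stratified_toy_matches_oracle(self):
        df = _toy(y=[1, 0, 1, 1, 0, 0, 1, 0],
                  weight=[1.0, 2.0, 1.5, 0.5, 2.0, 1.0, 3.0, 1.0],
                  stratum=["A"] * 4 + ["B"] * 4,
                  psu=["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"])
        est = weighted_prevalence(df)
        assert est.se == pytest.approx(linearized_se_oracle(df), abs=1e-10)

    def test_weighting_moves_the_point_estimate(self):
        df = _toy([1, 0], [3.0, 1.0], "s", ["p1", "p2"])
        assert weighted_prevalence(df).point == pytest.approx(75.0)

    def test_ci_truncated_to_percentage_scale(self):
        df = _toy([1, 0, 0, 0, 0, 0, 0, 0, 1, 0], 1.0, "s",
                  ["p1", "p2", "p3", "p4", "p5"] * 2)
        est = weighted_prevalence(df)
        assert 0.0 <= est.ci_low <= est.point <= est.ci_high <= 100.0

    def test_empty_denominator_reported_undefined(self):
        est = weighted_prevalence(_toy([], [], [], []))
        assert not est.defined
        assert np.isnan(est.point)

    def test_single_psu_stratum_contributes_nothing(self):
        df = _toy([1, 0, 1, 0], 1.0, ["A", "A", "B", "B"],
                  ["a1", "a1", "b1", "b2"])
        est = weighted_prevalence(df)  # stratum A has one PSU
        only_b = linearized_se_oracle(df)
        assert est.se == pytest.approx(only_b)

    def test_linearization_agrees_with_cluster_bootstrap(self):
        df = simulate_survey_replicate(0.25, n_strata=20, psus_per_stratum=4,
                                       persons_per_psu=40, seed=12)
        est = weighted_prevalence(df)
        boot = bootstrap_se(df, n_boot=500, seed=1)
        assert abs(boot - est.se) / est.se < 0.15


class TestCompareSources:
    def _est(self, point, se, measure="m", state="XX", source="a"):
        from statesurv.estimation import PrevalenceEstimate
        return PrevalenceEstimate(measure, state, source, point, se,
                                  max(0, point - 1.96 * se),
                                  min(100, point + 1.96 * se), 100, 1000.0)

    def test_identical_estimates(self):
        c = compare_sources(self._est(20, 2), self._est(20, 2, source="b"))
        assert c.t == 0.0 and c.p_value == pytest.approx(1.0)
        assert not c.significant

    def test_arithmetic_oracle(self):
        c = compare_sources(self._est(30, 2), self._est(20, 2, source="b"))
        assert c.t == pytest.approx(10 / np.sqrt(8))
        assert c.p_value < 0.01 and c.significant

    def test_zero_variance_equal_points_defined(self):
        c = compare_sources(self._est(50, 0), self._est(50, 0, source="b"))
        assert c.t == 0.0

    def test_mismatched_measures_rejected(self):
        with pytest.raises(ValueError, match="same measure"):
            compare_sources(self._est(10, 1, measure="x"),
                            self._est(10, 1, measure="y"))

    def test_satterthwaite_reference_optional(self):
        c_norm = compare_sources(self._est(25, 2), self._est(20, 2, source="b"))
        c_t = compare_sources(self._est(25, 2), self._est(20, 2, source="b"), df=5)
        assert c_t.p_value > c_norm.p_value


class TestReport:
    def _estimates(self):
        from statesurv.estimation import PrevalenceEstimate
        out = []
        for source, pt, se in (("ehr", 10.0, 1.0), ("national_survey", 20.0, 1.0),
                               ("panel_survey", 19.0, 1.0)):
            out.append(PrevalenceEstimate("diagnosed_diabetes", "XX", source,
                                          pt, se, pt - 2, pt + 2, 100, 1000.0))
        return out

    def test_below_both_flag_rendered_as_double_arrow(self):
        report = build_report(self._estimates())
        tidy = report["estimates"]
        row = tidy[(tidy["source"] == "ehr")].iloc[0]
        assert row["flag"] == "down2"
        assert row["arrow"] == "↓↓"
        nat = tidy[(tidy["source"] == "national_survey")].iloc[0]
        assert nat["flag"] == "up"  # above EHR only, not above panel

    def test_prevalence_table_has_ci_strings(self):
        report = build_report(self._estimates())
        table = report["prevalence"]
        assert "ehr_ci" in table.columns
        assert table["ehr_ci"].iloc[0] == "8.0, 12.0"

    def test_comparisons_enumerated_pairwise(self):
        report = build_report(self._estimates())
        assert len(report["comparisons"]) == 3

    def test_comorbidity_partition_sums_to_100(self, small_bundle):
        # weighted Both/Neither/exactly-one categories partition the
        # diabetes population: p_both + p_neither + (p_htn + p_chol - 2 p_both)
        from statesurv import classify_population, merge_ehr_tables
        src = merge_ehr_tables(small_bundle.ehr_tables)
        st = classify_population(src).statuses
        el = st[st["eligible"] & (st["diabetes"] != "none")]
        df = pd.DataFrame({
            "weight": 1.0, "stratum": "s", "psu": np.arange(len(el)) % 7,
            "htn": el["hypertension"].to_numpy(),
            "chol": el["high_cholesterol"].to_numpy()})
        p = {}
        for name, y in (("htn", df["htn"]), ("chol", df["chol"]),
                        ("both", df["htn"] & df["chol"]),
                        ("neither", ~df["htn"] & ~df["chol"])):
            p[name] = weighted_prevalence(df.assign(y=y.astype(float))).point
        total = p["both"] + p["neither"] + (p["htn"] + p["chol"] - 2 * p["both"])
        assert total == pytest.approx(100.0, abs=1e-9)
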