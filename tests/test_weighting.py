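"""Calibration weighting: IPF oracle equivalence, post-stratification,
propensity adjustment, trimming, and the conservation invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statesurv import (Raker, WeightSet, poststratify_counties,
                       propensity_adjust, rake, rake_to_state,
                       select_panel_strategy, trim_weights)


def naive_ipf(w, cells_a, targets_a, cells_b, targets_b, n_cycles=3000):
    """Brute-force iterative proportional fitting: adjust one margin at a
    time by plain dictionary arithmetic. Independent oracle for Raker."""
    w = np.asarray(w, dtype=float).copy()
    for _ in range(n_cycles):
        for cells, targets in ((cells_a, targets_a), (cells_b, targets_b)):
            totals = {}
            for c, wi in zip(cells, w):
                totals[c] = totals.get(c, 0.0) + wi
            w = np.array([wi * targets[c] / totals[c]
                          for c, wi in zip(cells, w)])
    return w


def _random_problem(rng, n_a=3, n_b=4, n=40):
    """Feasible two-margin raking problem: targets are the margins of a
    random positive population sharing the sample's support."""
    while True:
        a = rng.integers(0, n_a, n)
        b = rng.integers(0, n_b, n)
        if len(set(a)) == n_a and len(set(b)) == n_b:
            break
    w0 = rng.uniform(0.5, 2.0, n)
    v = rng.uniform(0.5, 3.0, n)  # population weights defining the targets
    ta = {i: v[a == i].sum() for i in range(n_a)}
    tb = {j: v[b == j].sum() for j in range(n_b)}
    X = pd.DataFrame({"a": a, "b": b})
    margins = [(("a",), pd.Series(ta)), (("b",), pd.Series(tb))]
    return X, w0, margins, (a, ta, b, tb)


class TestRaker:
    def test_independence_margins_converge_in_one_cycle(self):
        # 2x2 with product-form targets: row x col / N is the IPF limit
        X = pd.DataFrame({"r": [0, 0, 1, 1], "c": [0, 1, 0, 1]})
        margins = [(("r",), pd.Series({0: 60.0, 1: 40.0})),
                   (("c",), pd.Series({0: 30.0, 1: 70.0}))]
        raker = Raker(margins=margins).fit(X)
        assert raker.n_iter_ == 1
        expect = np.array([60 * 30, 60 * 70, 40 * 30, 40 * 70]) / 100.0
        np.testing.assert_allclose(raker.weights_, expect, rtol=1e-8)

    def test_satisfied_margins_need_zero_iterations(self):
        X = pd.DataFrame({"a": [0, 1]})
        raker = Raker(margins=[(("a",), pd.Series({0: 1.0, 1: 1.0}))]).fit(X)
        assert raker.n_iter_ == 0
        np.testing.assert_array_equal(raker.weights_, [1.0, 1.0])

    def test_2x3_toy_matches_brute_force(self):
        X = pd.DataFrame({"a": [0, 0, 0, 1, 1, 1], "b": [0, 1, 2, 0, 1, 2]})
        margins = [(("a",), pd.Series({0: 4.0, 1: 2.0})),
                   (("b",), pd.Series({0: 3.0, 1: 2.0, 2: 1.0}))]
        w = Raker(margins=margins, tol=1e-12).fit(X).weights_
        w_oracle = naive_ipf(np.ones(6), X["a"], {0: 4, 1: 2},
                             X["b"], {0: 3, 1: 2, 2: 1})
        np.testing.assert_allclose(w, w_oracle, atol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X, w0, margins, (a, ta, b, tb) = _random_problem(rng)
        w = Raker(margins=margins, tol=1e-12).fit(X, sample_weight=w0).weights_
        w_oracle = naive_ipf(w0, a, ta, b, tb)
        np.testing.assert_allclose(w, w_oracle, rtol=1e-8)

    def test_idempotent_and_conserving(self):
        rng = np.random.default_rng(8)
        X, w0, margins, _ = _random_problem(rng)
        w1 = Raker(margins=margins).fit(X, sample_weight=w0).weights_
        raker2 = Raker(margins=margins).fit(X, sample_weight=w1)
        assert raker2.n_iter_ == 0
        np.testing.assert_allclose(raker2.weights_, w1, rtol=1e-8)
        assert w1.sum() == pytest.approx(margins[0][1].sum(), rel=1e-8)

    def test_empty_cell_with_positive_target_rejected(self):
        X = pd.DataFrame({"a": [0, 0]})
        with pytest.raises(ValueError, match="empty sample cells"):
            Raker(margins=[(("a",), pd.Series({0: 5.0, 1: 5.0}))]).fit(X)

    def test_missing_margin_category_rejected(self):
        X = pd.DataFrame({"a": [0, np.nan]})
        with pytest.raises(ValueError, match="missing margin category"):
            Raker(margins=[(("a",), pd.Series({0.0: 5.0}))]).fit(X)

    def test_unknown_sample_cell_rejected(self):
        X = pd.DataFrame({"a": [0, 2]})
        with pytest.raises(ValueError, match="no target"):
            Raker(margins=[(("a",), pd.Series({0: 5.0, 1: 5.0}))]).fit(X)


def _county_df(rows):
    return pd.DataFrame(rows, columns=["person_id", "county", "age_band", "sex"])


def _margin_df(rows):
    return pd.DataFrame(rows, columns=["county", "age_band", "sex", "target"])


class TestCountyPostStratification:
    def test_single_cell_ratio(self):
        ehr = _county_df([(f"p{i}", "c1", "50-59", "female") for i in range(5)])
        marg = _margin_df([("c1", "50-59", "female", 1000)])
        ws = poststratify_counties(ehr, marg)
        np.testing.assert_allclose(ws.weights.to_numpy(), 200.0)

    def test_county_totals_proportional_to_population(self):
        ehr = _county_df([("p1", "c1", "50-59", "female"),
                          ("p2", "c1", "50-59", "male"),
                          ("p3", "c2", "50-59", "female"),
                          ("p4", "c2", "50-59", "male")])
        marg = _margin_df([("c1", "50-59", "female", 600), ("c1", "50-59", "male", 400),
                           ("c2", "50-59", "female", 2000), ("c2", "50-59", "male", 1000)])
        ws = poststratify_counties(ehr, marg)
        w = ws.weights
        assert w[["p1", "p2"]].sum() / w[["p3", "p4"]].sum() == pytest.approx(1 / 3)

    def test_empty_cell_collapses_to_age_band(self):
        # no sampled 50-59 males: band target pools and sex collapses
        ehr = _county_df([("p1", "c1", "50-59", "female"),
                          ("p2", "c1", "50-59", "female"),
                          ("p3", "c1", "60-69", "male")])
        marg = _margin_df([("c1", "50-59", "female", 300), ("c1", "50-59", "male", 100),
                           ("c1", "60-69", "male", 50)])
        ws = poststratify_counties(ehr, marg)
        w = ws.weights
        assert w["p1"] == pytest.approx(200.0)  # (300+100)/2
        assert w["p3"] == pytest.approx(50.0)
        assert w.sum() == pytest.approx(450.0)  # county total preserved
        assert ws.convergence["collapsed_cells"]

    def test_empty_band_merges_into_neighbor(self):
        ehr = _county_df([("p1", "c1", "60-69", "female")])
        marg = _margin_df([("c1", "50-59", "female", 100),
                           ("c1", "60-69", "female", 40)])
        ws = poststratify_counties(ehr, marg)
        assert ws.weights["p1"] == pytest.approx(140.0)

    def test_uncovered_margin_county_is_ignored_but_missing_margin_errors(self):
        ehr = _county_df([("p1", "c1", "50-59", "female")])
        marg = _margin_df([("c1", "50-59", "female", 10), ("c9", "50-59", "female", 99)])
        assert len(poststratify_counties(ehr, marg).weights) == 1
        with pytest.raises(ValueError, match="c1"):
            poststratify_counties(ehr, _margin_df([("c9", "50-59", "female", 99)]))


class TestTwoStepGeographic:
    def test_full_coverage_step2_is_noop(self):
        ehr = _county_df([("p1", "c1", "50-59", "female"),
                          ("p2", "c2", "50-59", "female")])
        ehr["state"] = "XX"
        marg = _margin_df([("c1", "50-59", "female", 100),
                           ("c2", "50-59", "female", 300)])
        state = pd.DataFrame({"state": ["XX"], "age_band": ["50-59"],
                              "sex": ["female"], "target": [400]})
        ws1 = poststratify_counties(ehr, marg)
        ws2 = rake_to_state(ehr, ws1, state)
        np.testing.assert_allclose(ws2.weights.to_numpy(),
                                   ws1.weights.to_numpy(), rtol=1e-8)

    def test_partial_coverage_total_equals_state_population(self):
        ehr = _county_df([("p1", "c1", "50-59", "female"),
                          ("p2", "c1", "60-69", "female")])
        ehr["state"] = "XX"
        marg = _margin_df([("c1", "50-59", "female", 100),
                           ("c1", "60-69", "female", 50)])
        state = pd.DataFrame({
            "state": ["XX", "XX"], "age_band": ["50-59", "60-69"],
            "sex": ["female", "female"], "target": [1000, 800]})
        ws2 = rake_to_state(ehr, poststratify_counties(ehr, marg), state)
        assert ws2.weights.sum() == pytest.approx(1800.0)
        assert ws2.provenance[-1] == "state-raked"


class TestPropensityAdjustment:
    def _sample(self, rng, n, probs):
        bands = rng.choice(["50-59", "60-69", "70-79", "80+"], n, p=probs)
        return pd.DataFrame({
            "person_id": [f"s{i}" for i in range(n)],
            "age_band": bands,
            "sex": rng.choice(["female", "male"], n),
            "base_weight": 1.0,
        })

    YOUNG = (0.4, 0.3, 0.2, 0.1)
    OLD = (0.1, 0.2, 0.3, 0.4)
    FLAT = (0.25, 0.25, 0.25, 0.25)

    def _margins(self, reference):
        out = []
        for var in ("age_band", "sex"):
            t = reference[var].value_counts()
            out.append(((var,), t.astype(float)))
        return out

    def test_identical_distributions_give_constant_factors(self, rng):
        sample = self._sample(rng, 3000, self.FLAT)
        reference = self._sample(rng, 3000, self.FLAT).drop(columns="base_weight")
        from statesurv import PropensityAdjuster
        adj = PropensityAdjuster(covariates=("age_band", "sex"))
        factor = adj.fit_transform(sample, reference)
        assert factor.std() / factor.mean() < 0.1

    def test_older_reference_upweights_older_respondents(self, rng):
        sample = self._sample(rng, 3000, self.YOUNG)
        reference = self._sample(rng, 3000, self.OLD).drop(columns="base_weight")
        ws = propensity_adjust(sample, reference, self._margins(reference),
                               pop_total=10_000.0,
                               covariates=("age_band", "sex"))
        df = sample.assign(w=ws.weights.to_numpy())
        means = df.groupby("age_band")["w"].mean()
        assert means["80+"] > means["60-69"] > means["50-59"]

    def test_weight_sum_equals_population_total(self, rng):
        sample = self._sample(rng, 2000, self.YOUNG)
        reference = self._sample(rng, 2000, self.OLD).drop(columns="base_weight")
        ws = propensity_adjust(sample, reference, self._margins(reference),
                               pop_total=54_321.0,
                               covariates=("age_band", "sex"))
        assert ws.weights.sum() == pytest.approx(54_321.0, rel=1e-8)
        assert ws.provenance == ["base", "propensity-adjusted", "raked", "scaled"]


class TestPanelStrategy:
    @pytest.fixture
    def panel(self):
        states = ["CA"] * 900 + ["AL"] * 80 + ["FL"] * 600
        return pd.DataFrame({"person_id": range(len(states)), "state": states})

    DIVS = {"CA": "west", "AL": "south", "FL": "south"}

    def test_large_state_direct(self, panel):
        sub, mode = select_panel_strategy(panel, "CA", self.DIVS)
        assert mode == "direct" and len(sub) == 900

    def test_small_state_uses_division(self, panel):
        sub, mode = select_panel_strategy(panel, "AL", self.DIVS)
        assert mode == "synthetic"
        assert set(sub["state"]) == {"AL", "FL"}

    def test_threshold_boundary_inclusive(self, panel):
        sub, mode = select_panel_strategy(panel, "FL", self.DIVS, threshold=600)
        assert mode == "direct"

    def test_empty_division_errors(self, panel):
        with pytest.raises(ValueError, match="division"):
            select_panel_strategy(panel, "MA", {"MA": "northeast"})


class TestTrimming:
    def test_infinite_factor_is_identity(self):
        ws = WeightSet(pd.Series([1.0, 2.0, 50.0], index=list("abc")))
        out = trim_weights(ws, np.inf)
        np.testing.assert_array_equal(out.weights.to_numpy(), [1, 2, 50])

    def test_equal_weights_identity(self):
        ws = WeightSet(pd.Series([3.0] * 5, index=list("abcde")))
        out = trim_weights(ws, 2.0)
        np.testing.assert_array_equal(out.weights.to_numpy(), [3.0] * 5)

    def test_toy_vector_against_hand_computation(self):
        # weights (1,1,2,2,30), factor 5 -> cap = median(2)*5 = 10; excess 20
        # spread over the four uncapped weights proportionally: x (1+20/6)
        ws = WeightSet(pd.Series([1.0, 1.0, 2.0, 2.0, 30.0], index=list("abcde")))
        out = trim_weights(ws, 5.0)
        scale = 1 + 20 / 6
        np.testing.assert_allclose(
            out.weights.to_numpy(),
            [scale, scale, 2 * scale, 2 * scale, 10.0], rtol=1e-10)
        assert out.weights.sum() == pytest.approx(36.0)
        assert out.convergence["n_trimmed"] == 1
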