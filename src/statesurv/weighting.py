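"""Calibration weighting: raking (IPF), county post-stratification, the
two-step geographic weighting for clustered EHR data, propensity adjustment
of national survey weights to state targets, and weight trimming.

A *margin* is a pair ``(columns, targets)``: the tuple of categorical columns
defining the cells, and a Series of nonnegative control totals indexed by
cell (a plain Index for one column, a MultiIndex for a cross-tabulation).
Raking multiplies weights so the weighted cell totals of every margin match
its targets simultaneously; post-stratification is the exact single-margin
special case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .config import AGE_BAND_LABELS

log = logging.getLogger(__name__)

Margin = tuple[tuple[str, ...], pd.Series]


@dataclass
class WeightSet:
    """Person-level weights with a provenance chain and convergence record."""

    weights: pd.Series  # indexed by person_id, strictly positive
    provenance: list[str] = field(default_factory=lambda: ["base"])
    convergence: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("all weights must be strictly positive")
        if not self.provenance:
            raise ValueError("provenance chain must be nonempty")

    def derive(self, weights: pd.Series, step: str, **conv) -> "WeightSet":
        out = WeightSet(weights, [*self.provenance, step],
                        {**self.convergence, **conv})
        out.validate()
        return out


def _cell_labels(X: pd.DataFrame, cols: tuple[str, ...]):
    for c in cols:
        if c not in X.columns:
            raise ValueError(f"margin column '{c}' missing from data")
        if X[c].isna().any():
            raise ValueError(f"person with missing margin category in '{c}'")
    if len(cols) == 1:
        return X[cols[0]]
    return pd.MultiIndex.from_frame(X[list(cols)])


class Raker(BaseEstimator):
    """Iterative proportional fitting of person weights to margin targets.

    fit(X, sample_weight) iterates cycles over the margins until every
    weighted cell total matches its target within ``tol`` (relative), then
    exposes ``weights_``, ``n_iter_`` (full cycles of adjustment) and
    ``max_dev_``. Margins already satisfied on entry converge in 0 cycles.
    """

    def __init__(self, margins: list[Margin] | None = None,
                 tol: float = 1e-8, max_iter: int = 500):
        self.margins = margins
        self.tol = tol
        self.max_iter = max_iter

    def _prepare(self, X: pd.DataFrame):
        prepared = []
        for cols, targets in self.margins:
            cols = tuple(cols)
            targets = pd.Series(targets)
            if (targets < 0).any():
                raise ValueError(f"negative target in margin {cols}")
            labels = _cell_labels(X, cols)
            codes = pd.Categorical(labels if isinstance(labels, pd.Series)
                                   else pd.Series(list(labels), index=X.index))
            unknown = set(codes.categories) - set(targets.index)
            if unknown:
                raise ValueError(
                    f"margin {cols}: sample cells {sorted(map(str, unknown))} "
                    "have no target")
            unreachable = [c for c in targets.index
                           if targets[c] > 0 and c not in set(codes.categories)]
            if unreachable:
                raise ValueError(
                    f"margin {cols}: empty sample cells with positive targets: "
                    f"{sorted(map(str, unreachable))}")
            t = targets.reindex(codes.categories).to_numpy(dtype=float)
            prepared.append((cols, codes.codes, t, len(codes.categories)))
        return prepared

    def fit(self, X: pd.DataFrame, y=None, sample_weight=None) -> "Raker":
        if not self.margins:
            raise ValueError("no margins supplied")
        w = (np.ones(len(X)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).copy())
        if (w <= 0).any():
            raise ValueError("sample weights must be strictly positive")
        prepared = self._prepare(X)
        # positive targets with no sample mass can never be matched
        for cols, codes, t, k in prepared:
            present = np.bincount(codes, minlength=k) > 0
            impossible = (~present) & (t > 0)
            if impossible.any():
                raise ValueError(
                    f"margin {cols}: empty sample cells with positive targets "
                    f"at positions {np.flatnonzero(impossible).tolist()}")

        def max_dev(weights: np.ndarray) -> float:
            dev = 0.0
            for _, codes, t, k in prepared:
                tot = np.bincount(codes, weights=weights, minlength=k)
                pos = t > 0
                dev = max(dev, np.max(np.abs(tot[pos] - t[pos]) / t[pos],
                                      initial=0.0))
            return dev

        n_iter = 0
        dev = max_dev(w)
        while dev > self.tol:
            if n_iter >= self.max_iter:
                raise RuntimeError(
                    f"raking failed to converge in {self.max_iter} cycles "
                    f"(max relative deviation {dev:.3e})")
            for _, codes, t, k in prepared:
                tot = np.bincount(codes, weights=w, minlength=k)
                factor = np.ones(k)
                pos = (t > 0) & (tot > 0)
                factor[pos] = t[pos] / tot[pos]
                w = w * factor[codes]
            n_iter += 1
            dev = max_dev(w)
        self.weights_ = w
        self.n_iter_ = n_iter
        self.max_dev_ = dev
        return self

    def fit_transform(self, X: pd.DataFrame, y=None, sample_weight=None) -> np.ndarray:
        return self.fit(X, sample_weight=sample_weight).weights_


def rake(wset: WeightSet, X: pd.DataFrame, margins: list[Margin],
         tol: float = 1e-8, max_iter: int = 500) -> WeightSet:
    """Rake an existing weight set to the margins; provenance-preserving."""
    raker = Raker(margins=margins, tol=tol, max_iter=max_iter)
    w = raker.fit_transform(X, sample_weight=wset.weights.reindex(X["person_id"]).to_numpy()
                            if "person_id" in X.columns else wset.weights.to_numpy())
    idx = X["person_id"] if "person_id" in X.columns else wset.weights.index
    return wset.derive(pd.Series(w, index=pd.Index(idx, name="person_id")), "raked",
                       iterations=raker.n_iter_, max_margin_deviation=raker.max_dev_)


def _collapsed_age_sex_cells(sub: pd.DataFrame, targets: pd.Series,
                             tag: str) -> tuple[pd.Series, dict[str, float], list[str]]:
    """Assign each person an age x sex calibration cell, collapsing cells the
    sample cannot support.

    ``targets`` is indexed by (age_band, sex). A cell with a positive target
    but no sample collapses its whole age band to a sex-pooled cell; an age
    band with no sample at all merges its target into the nearest band with
    sample. Returns (cell label per person, cell targets, collapse log)."""
    order = list(AGE_BAND_LABELS)
    cell_n = sub.groupby(["age_band", "sex"], observed=True).size()
    band_n = sub.groupby("age_band", observed=True).size()
    band_t = targets.groupby(level="age_band").sum()

    band_mode: dict[str, str] = {}
    collapsed: list[str] = []
    for band in band_t.index:
        empty_sex = any(targets.get((band, s), 0) > 0 and cell_n.get((band, s), 0) == 0
                        for s in ("female", "male"))
        if not empty_sex:
            band_mode[band] = "cell"
        elif band_n.get(band, 0) > 0:
            band_mode[band] = "band"
            collapsed.append(f"{tag}:{band}:sex-pooled")
        else:
            band_mode[band] = "merge"

    extra_target: dict[str, float] = {}
    for band, mode in list(band_mode.items()):
        if mode != "merge":
            continue
        pos = order.index(band)
        host = None
        for dist in range(1, len(order)):
            for cand in (pos - dist, pos + dist):
                if 0 <= cand < len(order) and band_n.get(order[cand], 0) > 0:
                    host = order[cand]
                    break
            if host:
                break
        if host is None:
            raise ValueError(f"{tag}: margin targets but no sample at all")
        extra_target[host] = extra_target.get(host, 0.0) + float(band_t[band])
        collapsed.append(f"{tag}:{band}:merged-into-{host}")
        if band_mode[host] == "cell":
            band_mode[host] = "band"
            collapsed.append(f"{tag}:{host}:sex-pooled")

    cell_targets: dict[str, float] = {}
    for band, mode in band_mode.items():
        if mode == "merge":
            continue
        if mode == "cell":
            for s in ("female", "male"):
                if cell_n.get((band, s), 0) > 0:
                    cell_targets[f"{band}|{s}"] = float(targets.get((band, s), 0.0))
        else:
            cell_targets[band] = float(band_t[band]) + extra_target.get(band, 0.0)

    labels = np.where(
        sub["age_band"].map(lambda b: band_mode.get(b) == "cell"),
        sub["age_band"].astype(str) + "|" + sub["sex"].astype(str),
        sub["age_band"].astype(str))
    return pd.Series(labels, index=sub.index), cell_targets, collapsed


class CountyPostStratifier(BaseEstimator):
    """Exact ratio adjustment of EHR persons to county age x sex totals.

    ``county_margins`` has columns (county, age_band, sex, target). Within
    each represented county every age x sex cell receives weight
    target / sample count, so the county's total weight equals its total
    population. A cell with a positive target but no sample is collapsed to
    the county age-band margin (sex pooled), and an empty age band is merged
    into the nearest non-empty band; collapses are logged and recorded in
    ``collapsed_``.
    """

    def __init__(self, county_margins: pd.DataFrame | None = None):
        self.county_margins = county_margins

    def fit(self, X: pd.DataFrame, y=None) -> "CountyPostStratifier":
        need = {"county", "age_band", "sex"}
        if not need.issubset(X.columns):
            raise ValueError(f"need columns {sorted(need)}")
        marg = self.county_margins
        covered = set(X["county"])
        missing = covered - set(marg["county"])
        if missing:
            raise ValueError(f"no county margins for counties {sorted(missing)}")
        w = np.full(len(X), np.nan)
        collapsed: list[str] = []
        for county, sub_idx in X.groupby("county").groups.items():
            sub = X.loc[sub_idx]
            targets = (marg[marg["county"] == county]
                       .set_index(["age_band", "sex"])["target"])
            labels, cell_targets, clog = _collapsed_age_sex_cells(sub, targets,
                                                                  str(county))
            collapsed += clog
            counts = labels.value_counts()
            cell_w = {c: cell_targets[c] / counts[c] for c in counts.index}
            w[X.index.get_indexer(sub_idx)] = labels.map(cell_w).to_numpy()
        if np.isnan(w).any():
            raise RuntimeError("internal error: unweighted persons remain")
        if collapsed:
            log.info("county post-stratification collapsed cells: %s", collapsed)
        self.weights_ = w
        self.collapsed_ = collapsed
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).weights_


def poststratify_counties(ehr: pd.DataFrame, county_margins: pd.DataFrame) -> WeightSet:
    """Step 1 of the EHR geographic weighting."""
    ps = CountyPostStratifier(county_margins)
    w = ps.fit_transform(ehr)
    ws = WeightSet(pd.Series(w, index=pd.Index(ehr["person_id"], name="person_id")),
                   ["base", "county-poststratified"],
                   {"collapsed_cells": ps.collapsed_})
    ws.validate()
    return ws


def rake_to_state(ehr: pd.DataFrame, wset: WeightSet, state_margins: pd.DataFrame,
                  tol: float = 1e-8, max_iter: int = 500) -> WeightSet:
    """Step 2: rake county-weighted EHR totals to the state age x sex totals
    of the office-visit population. ``state_margins`` has columns
    (state, age_band, sex, target); states are processed independently.
    Age x sex cells the sample cannot support are collapsed the same way as
    in the county step (sex pooled, then neighboring bands merged)."""
    w = wset.weights.reindex(ehr["person_id"]).to_numpy().copy()
    iters, devs, collapsed = {}, {}, []
    for state, idx in ehr.groupby("state").groups.items():
        sub = ehr.loc[idx]
        targets = (state_margins[state_margins["state"] == state]
                   .set_index(["age_band", "sex"])["target"])
        labels, cell_targets, clog = _collapsed_age_sex_cells(sub, targets,
                                                              str(state))
        collapsed += clog
        raker = Raker(margins=[(("cell_",), pd.Series(cell_targets))],
                      tol=tol, max_iter=max_iter)
        pos = ehr.index.get_indexer(idx)
        w[pos] = raker.fit_transform(sub.assign(cell_=labels),
                                     sample_weight=w[pos])
        iters[state] = raker.n_iter_
        devs[state] = raker.max_dev_
    return wset.derive(pd.Series(w, index=pd.Index(ehr["person_id"], name="person_id")),
                       "state-raked", state_iterations=iters, state_deviation=devs,
                       state_collapsed_cells=collapsed)


class PropensityAdjuster(BaseEstimator):
    """Odds-of-membership reweighting of a national sample toward a state.

    A main-effects logistic regression distinguishes the state reference
    sample (label 1) from the national sample (label 0) on the harmonized
    covariates; each national person's base weight is multiplied by the
    fitted odds p / (1 - p). Raking to the state margins follows separately.
    """

    def __init__(self, covariates: tuple[str, ...] = ("age_band", "sex", "race_eth",
                                                      "insurance", "education",
                                                      "health_status"),
                 overlap_eps: float = 1e-8):
        self.covariates = covariates
        self.overlap_eps = overlap_eps

    def fit(self, sample: pd.DataFrame, reference: pd.DataFrame) -> "PropensityAdjuster":
        cols = [c for c in self.covariates if c in sample.columns and c in reference.columns]
        if not cols:
            raise ValueError("no propensity covariates present in both frames")
        stacked = pd.concat([sample[cols], reference[cols]],
                            ignore_index=True).astype(str)
        design = pd.get_dummies(stacked, drop_first=True).astype(float)
        ds = design.iloc[: len(sample)]
        y = np.r_[np.zeros(len(sample)), np.ones(len(reference))]
        model = LogisticRegression(C=np.inf, max_iter=2000)
        model.fit(design.to_numpy(), y)
        p = model.predict_proba(ds.to_numpy())[:, 1]
        if np.any(p <= self.overlap_eps) or np.any(p >= 1 - self.overlap_eps):
            k = int(np.sum((p <= self.overlap_eps) | (p >= 1 - self.overlap_eps)))
            raise ValueError(
                f"propensity non-overlap: {k} sample persons with predicted "
                f"membership probability at 0 or 1; check covariate support")
        self.model_ = model
        self.feature_names_ = list(design.columns)
        self.factor_ = p / (1.0 - p)
        return self

    def fit_transform(self, sample: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
        return self.fit(sample, reference).factor_


def propensity_adjust(sample: pd.DataFrame, reference: pd.DataFrame,
                      margins: list[Margin], pop_total: float,
                      covariates: tuple[str, ...] | None = None,
                      tol: float = 1e-8, max_iter: int = 500) -> WeightSet:
    """Propensity-adjust national base weights toward a state, rake to the
    state margins, and scale so the weights sum to the state population."""
    kwargs = {} if covariates is None else {"covariates": covariates}
    adj = PropensityAdjuster(**kwargs)
    factor = adj.fit_transform(sample, reference)
    w = sample["base_weight"].to_numpy(dtype=float) * factor
    raker = Raker(margins=margins, tol=tol, max_iter=max_iter)
    w = raker.fit_transform(sample, sample_weight=w)
    w = w * (pop_total / w.sum())
    ws = WeightSet(pd.Series(w, index=pd.Index(sample["person_id"], name="person_id")),
                   ["base", "propensity-adjusted", "raked", "scaled"],
                   {"iterations": raker.n_iter_, "max_margin_deviation": raker.max_dev_})
    ws.validate()
    return ws


def select_panel_strategy(panel: pd.DataFrame, state: str,
                          divisions: dict[str, str],
                          threshold: int = 500) -> tuple[pd.DataFrame, str]:
    """Direct in-state estimation when the panel has at least ``threshold``
    respondents in the state (inclusive), else a synthetic estimate from the
    state's census division."""
    in_state = panel[panel["state"] == state]
    if len(in_state) >= threshold:
        return in_state.reset_index(drop=True), "direct"
    division = divisions[state]
    members = {s for s, d in divisions.items() if d == division}
    sub = panel[panel["state"].isin(members)]
    if not len(sub):
        raise ValueError(f"empty census-division subsample for state {state}")
    return sub.reset_index(drop=True), "synthetic"


class WeightTrimmer(BaseEstimator):
    """Cap weights above median x factor and redistribute the excess
    proportionally over the uncapped weights, conserving the total."""

    def __init__(self, factor: float = 20.0):
        self.factor = factor

    def fit(self, X=None, y=None, sample_weight=None) -> "WeightTrimmer":
        w = np.asarray(sample_weight, dtype=float).copy()
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        if not np.isfinite(self.factor):
            self.weights_, self.n_trimmed_ = w, 0
            return self
        total = w.sum()
        n_trimmed = 0
        for _ in range(50):
            cap = np.median(w) * self.factor
            over = w > cap
            if not over.any():
                break
            n_trimmed = int(over.sum())
            excess = (w[over] - cap).sum()
            w[over] = cap
            under = ~over
            w[under] *= 1.0 + excess / w[under].sum()
        w *= total / w.sum()
        self.weights_ = w
        self.n_trimmed_ = n_trimmed
        return self


def trim_weights(wset: WeightSet, factor: float,
                 X: pd.DataFrame | None = None,
                 margins: list[Margin] | None = None,
                 tol: float = 1e-8, max_iter: int = 500) -> WeightSet:
    """Trim a weight set; optionally re-rake to margins afterwards."""
    trimmer = WeightTrimmer(factor=factor)
    trimmer.fit(sample_weight=wset.weights.to_numpy())
    out = wset.derive(pd.Series(trimmer.weights_, index=wset.weights.index),
                      "trimmed", n_trimmed=trimmer.n_trimmed_)
    if margins and X is not None:
        out = rake(out, X, margins, tol=tol, max_iter=max_iter)
    return out
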