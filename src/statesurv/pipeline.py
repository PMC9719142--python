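"""End-to-end pipeline: simulate -> harmonize -> classify -> impute ->
weight -> estimate -> report.

Each stage is pure given its inputs and the run seed; a failure aborts the
run with the stage name attached. ``run_pipeline`` returns everything in
memory and can optionally write the full artifact set (harmonized tables,
weight sets with convergence logs, status tables, the three report tables,
and a truth-recovery summary) as CSV/JSON/markdown.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .casedefs import ClassifiedPopulation, classify_population
from .config import RunConfig, age_band
from .estimation import (PrevalenceEstimate, build_report, combine_mi_estimates,
                         report_markdown, weighted_prevalence)
from .harmonize import (HarmonizedSource, harmonize_survey, merge_ehr_tables,
                        write_harmonized)
from .impute import FpgImputer, impute_undiagnosed
from .synthetic import SyntheticBundle, generate_bundle
from .weighting import (WeightSet, poststratify_counties, propensity_adjust,
                        rake_to_state, select_panel_strategy, trim_weights)

log = logging.getLogger(__name__)

SOURCES = ("national_survey", "panel_survey", "ehr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    bundle: SyntheticBundle
    harmonized: dict[str, HarmonizedSource]
    classified: dict[str, ClassifiedPopulation]
    weights: dict[str, object]
    panel_modes: dict[str, str]
    estimates: list[PrevalenceEstimate]
    report: dict[str, pd.DataFrame]
    recovery: pd.DataFrame
    completeness: pd.DataFrame
    convergence: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("harmonize")
def _harmonize(bundle: SyntheticBundle, cfg: RunConfig) -> dict[str, HarmonizedSource]:
    return {
        "ehr": merge_ehr_tables(bundle.ehr_tables, cfg.index_date),
        "national_survey": harmonize_survey(bundle.national_survey, "national_survey"),
        "panel_survey": harmonize_survey(bundle.panel_survey, "panel_survey"),
    }


@_stage("classify")
def _classify(harmonized, cfg: RunConfig) -> dict[str, ClassifiedPopulation]:
    return {name: classify_population(src, cfg.windows, cfg.cutpoints)
            for name, src in harmonized.items()}


def _imputation_frame(src: HarmonizedSource, cp: ClassifiedPopulation) -> pd.DataFrame:
    """Person-level frame with a1c/fpg/diagnosed aligned to persons order."""
    wide = (src.labs.pivot_table(index="person_id", columns="analyte",
                                 values="value", aggfunc="last")
            if len(src.labs) else pd.DataFrame())
    df = src.persons[["person_id", "age", "sex"]].copy()
    for col in ("a1c", "fpg"):
        df[col] = df["person_id"].map(wide[col]) if col in wide.columns else np.nan
    diag = cp.statuses.set_index("person_id")["diabetes"] == "diagnosed"
    df["diagnosed"] = df["person_id"].map(diag).astype(bool)
    return df


@_stage("impute")
def _impute(harmonized, classified, cfg: RunConfig, rng: np.random.Generator):
    """Fit the elevated-FPG model on the national FPG half-sample and draw
    m completions of the undiagnosed indicator for both survey sources."""
    if not cfg.imputation:
        return None, {}
    frames = {s: _imputation_frame(harmonized[s], classified[s])
              for s in ("national_survey", "panel_survey")}
    natl = frames["national_survey"]
    model = FpgImputer(predictors=cfg.imputation_predictors, cuts=cfg.cutpoints)
    model.fit(natl, sample_weight=harmonized["national_survey"]
              .persons["base_weight"].to_numpy())
    completions = {
        s: impute_undiagnosed(frames[s], model, cfg.n_imputations, rng,
                              cuts=cfg.cutpoints)
        for s in frames
    }
    return model, completions


def _margins_for_state(bundle: SyntheticBundle, state: str):
    sm = bundle.margins["state_margins"]
    sub = sm[sm["state"] == state]
    return [((var,), g.set_index("cell")["target"])
            for var, g in sub.groupby("variable")]


@_stage("weight")
def _weight(bundle: SyntheticBundle, harmonized, classified, cfg: RunConfig):
    weights: dict[str, object] = {}
    convergence: dict[str, object] = {}
    panel_modes: dict[str, str] = {}

    # --- EHR: county post-stratification then raking to state office-visit totals
    ehr_p = harmonized["ehr"].persons
    ehr_el = ehr_p[classified["ehr"].statuses["eligible"].to_numpy()].copy()
    ehr_el["age_band"] = ehr_el["age"].map(age_band)
    step1 = poststratify_counties(ehr_el, bundle.margins["county_age_sex"])
    step2 = rake_to_state(ehr_el, step1, bundle.margins["state_age_sex_officevisit"],
                          tol=cfg.rake_tol, max_iter=cfg.rake_max_iter)
    weights["ehr"] = step2
    convergence["ehr"] = step2.convergence

    # --- national survey: per-state propensity adjustment + raking
    natl = harmonized["national_survey"].persons.copy()
    natl["age_band"] = natl["age"].map(age_band)
    pop_totals = bundle.census.groupby("state").size()
    natl_w: dict[str, WeightSet] = {}
    for state in bundle.config.states:
        ws = propensity_adjust(natl, bundle.reference[state],
                               _margins_for_state(bundle, state),
                               float(pop_totals[state]),
                               tol=cfg.rake_tol, max_iter=cfg.rake_max_iter)
        if np.isfinite(cfg.trim_factor):
            ws = trim_weights(ws, cfg.trim_factor, X=natl,
                              margins=_margins_for_state(bundle, state),
                              tol=cfg.rake_tol, max_iter=cfg.rake_max_iter)
        natl_w[state] = ws
        convergence[f"national_survey:{state}"] = ws.convergence
    weights["national_survey"] = natl_w

    # --- panel survey: direct where the state sample is large enough,
    # census-division synthetic estimation otherwise
    panel = harmonized["panel_survey"].persons.copy()
    panel["age_band"] = panel["age"].map(age_band)
    panel_w: dict[str, tuple[pd.DataFrame, WeightSet]] = {}
    for state in bundle.config.states:
        sub, mode = select_panel_strategy(panel, state, bundle.config.divisions,
                                          cfg.panel_threshold)
        panel_modes[state] = mode
        if mode == "direct":
            ws = WeightSet(pd.Series(sub["base_weight"].to_numpy(),
                                     index=pd.Index(sub["person_id"],
                                                    name="person_id")))
        else:
            ws = propensity_adjust(sub, bundle.reference[state],
                                   _margins_for_state(bundle, state),
                                   float(pop_totals[state]),
                                   tol=cfg.rake_tol, max_iter=cfg.rake_max_iter)
            convergence[f"panel_survey:{state}"] = ws.convergence
        panel_w[state] = (sub, ws)
    weights["panel_survey"] = panel_w
    return weights, convergence, panel_modes


def _measure_frame(persons: pd.DataFrame, statuses: pd.DataFrame,
                   weights: pd.Series) -> pd.DataFrame:
    df = persons.merge(statuses.drop(columns=["source"]), on="person_id")
    df["weight"] = df["person_id"].map(weights)
    return df[df["eligible"] & df["weight"].notna()].reset_index(drop=True)


def _estimates_for(df: pd.DataFrame, state: str, source: str,
                   undiag_mat: np.ndarray | None) -> list[PrevalenceEstimate]:
    """All measures for one (source, state) analysis frame.

    ``undiag_mat`` holds per-completion undiagnosed indicators aligned to
    ``df`` rows; when absent the observed classification is used directly.
    """
    out: list[PrevalenceEstimate] = []
    kw = dict(weight="weight", stratum="stratum", psu="psu",
              state=state, source=source)
    diagnosed = (df["diabetes"] == "diagnosed").astype(float)
    out.append(weighted_prevalence(df.assign(y=diagnosed), measure="diagnosed_diabetes",
                                   denominator="eligible", **kw))

    def _mi(measure, denominator, build):
        """build(und) -> (denominator mask, indicator); Rubin-combined."""
        if undiag_mat is None:
            und = (df["diabetes"] == "undiagnosed").to_numpy()
            mask, y = build(und)
            est = weighted_prevalence(df[mask].assign(y=y[mask].astype(float)),
                                      measure=measure, denominator=denominator, **kw)
            return est
        ests = []
        for j in range(undiag_mat.shape[1]):
            mask, y = build(undiag_mat[:, j])
            ests.append(weighted_prevalence(df[mask].assign(y=y[mask].astype(float)),
                                            measure=measure,
                                            denominator=denominator, **kw))
        return combine_mi_estimates(ests)

    diag = (df["diabetes"] == "diagnosed").to_numpy()
    all_rows = np.ones(len(df), dtype=bool)
    out.append(_mi("undiagnosed_diabetes", "eligible",
                   lambda und: (all_rows, und & ~diag)))

    htn = df["hypertension"].to_numpy(dtype=bool)
    chol = df["high_cholesterol"].to_numpy(dtype=bool)
    for measure, y in (("hypertension", htn), ("high_cholesterol", chol),
                       ("both", htn & chol), ("neither", ~htn & ~chol)):
        out.append(_mi(measure, "diabetes population",
                       lambda und, y=y: (diag | (und & ~diag), y)))

    # ABC control among the diagnosed, tested-only denominators
    a1c_ok = df["a1c_control"].to_numpy() != "untested"
    bp_ok = df["bp_control"].to_numpy() != "untested"
    chol_ok = df["chol_control"].to_numpy() != "untested"
    for measure, tested, good in (
        ("a1c_control", a1c_ok, df["a1c_control"].to_numpy() == "in_control"),
        ("bp_control", bp_ok, df["bp_control"].to_numpy() == "in_control"),
        ("chol_control", chol_ok, df["chol_control"].to_numpy() == "in_control"),
    ):
        mask = diag & tested
        out.append(weighted_prevalence(df[mask].assign(y=good[mask].astype(float)),
                                       measure=measure,
                                       denominator="diagnosed, tested", **kw))
    all_tested = diag & a1c_ok & bp_ok & chol_ok
    all_good = ((df["a1c_control"].to_numpy() == "in_control")
                & (df["bp_control"].to_numpy() == "in_control")
                & (df["chol_control"].to_numpy() == "in_control"))
    out.append(weighted_prevalence(
        df[all_tested].assign(y=all_good[all_tested].astype(float)),
        measure="all_three", denominator="diagnosed, tested on all three", **kw))
    return out


@_stage("estimate")
def _estimate(bundle, harmonized, classified, weights, completions,
              cfg: RunConfig) -> list[PrevalenceEstimate]:
    estimates: list[PrevalenceEstimate] = []
    for state in bundle.config.states:
        # EHR: in-state rows of the two-step weight set
        ehr_df = _measure_frame(harmonized["ehr"].persons,
                                classified["ehr"].statuses,
                                weights["ehr"].weights)
        ehr_df = ehr_df[ehr_df["state"] == state].reset_index(drop=True)
        estimates += _estimates_for(ehr_df, state, "ehr", None)

        # national survey: whole sample reweighted toward this state
        nat = harmonized["national_survey"]
        nat_df = _measure_frame(nat.persons, classified["national_survey"].statuses,
                                weights["national_survey"][state].weights)
        und = completions.get("national_survey")
        und_mat = None
        if und is not None:
            pos = nat.persons.reset_index(drop=True)
            lookup = pd.Series(np.arange(len(pos)), index=pos["person_id"])
            und_mat = und[lookup[nat_df["person_id"]].to_numpy()]
        estimates += _estimates_for(nat_df, state, "national_survey", und_mat)

        # panel survey: direct or division-synthetic subsample
        sub, ws = weights["panel_survey"][state]
        pan = harmonized["panel_survey"]
        pan_df = _measure_frame(sub, classified["panel_survey"].statuses, ws.weights)
        und = completions.get("panel_survey")
        und_mat = None
        if und is not None:
            pos = pan.persons.reset_index(drop=True)
            lookup = pd.Series(np.arange(len(pos)), index=pos["person_id"])
            und_mat = und[lookup[pan_df["person_id"]].to_numpy()]
        estimates += _estimates_for(pan_df, state, "panel_survey", und_mat)
    return estimates


def _completeness(harmonized, classified) -> pd.DataFrame:
    """Fraction of diagnosed EHR patients with each ABC measured in the
    control window (the non-random testing pattern the EHR source carries)."""
    st = classified["ehr"].statuses
    diag = st[st["eligible"] & (st["diabetes"] == "diagnosed")]
    if not len(diag):
        return pd.DataFrame()
    a1c = (diag["a1c_control"] != "untested").mean()
    bp = (diag["bp_control"] != "untested").mean()
    chol = (diag["chol_control"] != "untested").mean()
    al = ((diag["a1c_control"] != "untested") & (diag["bp_control"] != "untested")
          & (diag["chol_control"] != "untested")).mean()
    return pd.DataFrame([{"a1c_pct": 100 * a1c, "bp_pct": 100 * bp,
                          "chol_pct": 100 * chol, "all_three_pct": 100 * al,
                          "n_diagnosed": len(diag)}])


_TRUTH_COL = {"diagnosed_diabetes": "diagnosed", "undiagnosed_diabetes": "undiagnosed",
              "hypertension": "htn_given_diabetes",
              "high_cholesterol": "hichol_given_diabetes",
              "both": "both_given_diabetes", "neither": "neither_given_diabetes",
              "a1c_control": "a1c_control", "bp_control": "bp_control",
              "chol_control": "chol_control"}


def _recovery(estimates: list[PrevalenceEstimate], truth: pd.DataFrame) -> pd.DataFrame:
    t = truth.set_index("state")
    rows = []
    for e in estimates:
        col = _TRUTH_COL.get(e.measure)
        if col is None or not e.defined:
            continue
        tv = 100.0 * float(t.loc[e.state, col])
        rows.append({"measure": e.measure, "state": e.state, "source": e.source,
                     "estimate": e.point, "truth": tv, "error": e.point - tv,
                     "ci_covers": bool(e.ci_low <= tv <= e.ci_high)})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, bundle: SyntheticBundle | None = None,
                 write: bool = False) -> PipelineResult:
    """Run the full surveillance pipeline. Deterministic given (cfg, seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    if bundle is None:
        try:
            bundle = generate_bundle(cfg.truth, cfg.seed)
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate", exc) from exc

    harmonized = _harmonize(bundle, cfg)
    classified = _classify(harmonized, cfg)
    model, completions = _impute(harmonized, classified, cfg, rng)
    weights, convergence, panel_modes = _weight(bundle, harmonized, classified, cfg)
    estimates = _estimate(bundle, harmonized, classified, weights, completions, cfg)
    completeness = _completeness(harmonized, classified)
    report = build_report(estimates, alpha=cfg.alpha, completeness=completeness)
    recovery = _recovery(estimates, bundle.truth)

    result = PipelineResult(bundle, harmonized, classified, weights, panel_modes,
                            estimates, report, recovery, completeness, convergence)
    if write:
        _write_outputs(result, cfg, model)
    return result


@_stage("write")
def _write_outputs(result: PipelineResult, cfg: RunConfig, model) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for src in result.harmonized.values():
        write_harmonized(src, out / "harmonized")
    for name, cp in result.classified.items():
        cp.statuses.to_csv(out / f"statuses_{name}.csv", index=False)
    wdir = out / "weights"
    wdir.mkdir(exist_ok=True)
    ehr_ws = result.weights["ehr"]
    ehr_ws.weights.rename("weight").reset_index().assign(
        provenance=" -> ".join(ehr_ws.provenance)).to_csv(
        wdir / "ehr.csv", index=False)
    for state, ws in result.weights["national_survey"].items():
        ws.weights.rename("weight").reset_index().assign(
            provenance=" -> ".join(ws.provenance)).to_csv(
            wdir / f"national_{state}.csv", index=False)
    for state, (sub, ws) in result.weights["panel_survey"].items():
        ws.weights.rename("weight").reset_index().assign(
            provenance=" -> ".join(ws.provenance)).to_csv(
            wdir / f"panel_{state}.csv", index=False)
    for name in ("estimates", "comparisons", "prevalence", "comorbidity", "control"):
        df = result.report.get(name)
        if df is not None and len(df):
            df.to_csv(out / f"report_{name}.csv", index=False)
    result.recovery.to_csv(out / "recovery.csv", index=False)
    if len(result.completeness):
        result.completeness.to_csv(out / "completeness.csv", index=False)
    (out / "report.md").write_text(report_markdown(result.report))
    if model is not None:
        model.to_json(out / "fpg_model.json")
    with open(out / "run_manifest.json", "w") as fh:
        json.dump({"seed": cfg.seed, "panel_modes": result.panel_modes,
                   "convergence": result.convergence,
                   "manifest": result.bundle.manifest}, fh, indent=2, default=str)
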