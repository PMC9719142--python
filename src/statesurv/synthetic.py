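"""Synthetic population, EHR extract, and survey samples with known truth.

The generator simulates a census of adults age 50+ in a handful of states,
assigns diabetes status, comorbidities and control status from configured
ground-truth probabilities, and then derives the three analytic data sources
from that single population:

* an EHR extract as six linked raw tables (visits, diagnoses, labs,
  prescriptions, providers, demographics), covering only the counties where
  the clinic network operates, with non-random biomarker measurement;
* a national examination survey (stratified two-stage cluster sample with
  design weights; fasting glucose measured on a random half of respondents);
* a state-identified panel survey of the 50+ population (no fasting glucose).

Biomarker values are drawn from truncated normals conditional on status, so
that a fully measured, fully recorded population classifies exactly back to
the generating truth — the property every downstream recovery test leans on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import (
    AGE_BAND_LABELS,
    AGE_BANDS,
    EDUCATION_LEVELS,
    HEALTH_LEVELS,
    INSURANCE_LEVELS,
    RACE_LEVELS,
    SEXES,
    TruthConfig,
)

# base age-band shares before county tilt (older bands thinner)
_BASE_AGE_SHARES = np.array([0.35, 0.30, 0.22, 0.13])

# covariate base distributions; health status depends on diabetes below
_RACE_P = np.array([0.62, 0.13, 0.17, 0.08])
_INSURANCE_P = np.array([0.45, 0.38, 0.10, 0.07])
_EDUCATION_P = np.array([0.13, 0.28, 0.31, 0.28])
_HEALTH_P_DIAB = np.array([0.15, 0.40, 0.45])
_HEALTH_P_NONE = np.array([0.42, 0.40, 0.18])

# prescription recording rates for true hypertension / high-cholesterol cases
_P_RX_HTN = 0.65
_P_RX_CHOL = 0.60


def _draw_trunc(rng: np.random.Generator, params: tuple[float, float, float, float],
                size: int) -> np.ndarray:
    mean, sd, lo, hi = params
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _categorical(rng: np.random.Generator, levels, probs, size: int) -> np.ndarray:
    return rng.choice(np.asarray(levels, dtype=object), size=size, p=np.asarray(probs))


@dataclass
class SyntheticBundle:
    """All generated artifacts for one (config, seed) draw."""

    ehr_tables: dict[str, pd.DataFrame]
    national_survey: pd.DataFrame
    panel_survey: pd.DataFrame
    margins: dict[str, pd.DataFrame]
    reference: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    census: pd.DataFrame
    config: TruthConfig
    seed: int
    manifest: dict = field(default_factory=dict)


def simulate_census(config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the 50+ resident population of every configured state.

    Diabetes risk carries an age gradient (``config.age_rr``) and a county
    random effect; both multipliers are normalized against the realized
    state population so the expected state prevalence equals the configured
    truth exactly.
    """
    bm = config.biomarkers
    frames = []
    for state, st in config.states.items():
        n = st.population
        counties = [f"{state}-c{i:02d}" for i in range(st.n_counties)]
        # county sizes: roughly equal with mild variation
        shares = rng.dirichlet(np.full(st.n_counties, 30.0))
        county_of = rng.choice(st.n_counties, size=n, p=shares)

        tilt = np.asarray(st.county_age_tilt if st.county_age_tilt is not None
                          else np.zeros(st.n_counties))
        band_idx = np.empty(n, dtype=int)
        for c in range(st.n_counties):
            mask = county_of == c
            p = _BASE_AGE_SHARES * np.exp(-tilt[c] * np.arange(len(AGE_BANDS)))
            p = p / p.sum()
            band_idx[mask] = rng.choice(len(AGE_BANDS), size=mask.sum(), p=p)
        lo = np.array([b[0] for b in AGE_BANDS])
        hi = np.array([b[1] for b in AGE_BANDS])
        age = rng.integers(lo[band_idx], hi[band_idx] + 1)

        sex = _categorical(rng, SEXES, [0.54, 0.46], n)
        race = _categorical(rng, RACE_LEVELS, _RACE_P, n)
        insurance = _categorical(rng, INSURANCE_LEVELS, _INSURANCE_P, n)
        education = _categorical(rng, EDUCATION_LEVELS, _EDUCATION_P, n)

        visit_p = np.asarray(config.office_visit_rate)[band_idx]
        office_visit = rng.random(n) < visit_p
        pregnant = np.zeros(n, dtype=bool)
        if config.pregnancy_rate > 0:
            cand = (sex == "female") & (age < config.pregnancy_age_cap)
            pregnant[cand] = rng.random(cand.sum()) < config.pregnancy_rate

        # diabetes with normalized age x county multiplier
        u = rng.normal(0.0, config.cluster_sd, st.n_counties)
        mult = np.asarray(config.age_rr)[band_idx] * np.exp(u)[county_of]
        mult = mult / mult.mean()
        p_diab = np.clip((st.diagnosed + st.undiagnosed) * mult, 0.0, 1.0)
        diabetic = rng.random(n) < p_diab
        frac_diag = st.diagnosed / (st.diagnosed + st.undiagnosed) \
            if st.diagnosed + st.undiagnosed > 0 else 0.0
        diagnosed = diabetic & (rng.random(n) < frac_diag)
        undiag = diabetic & ~diagnosed
        diabetes = np.where(diagnosed, "diagnosed", np.where(undiag, "undiagnosed", "none"))

        health = np.empty(n, dtype=object)
        health[diabetic] = _categorical(rng, HEALTH_LEVELS, _HEALTH_P_DIAB, int(diabetic.sum()))
        health[~diabetic] = _categorical(rng, HEALTH_LEVELS, _HEALTH_P_NONE, int((~diabetic).sum()))

        htn = np.where(diabetic, rng.random(n) < st.htn_given_diabetes,
                       rng.random(n) < st.htn_background)
        hichol = np.where(diabetic, rng.random(n) < st.hichol_given_diabetes,
                          rng.random(n) < st.hichol_background)

        # within-case "not controlled" rates calibrated so control among the
        # diagnosed equals the configured target; non-cases are always in range
        bp_elev_rate = (1.0 - st.bp_control) / st.htn_given_diabetes
        chol_elev_rate = (1.0 - st.chol_control) / st.hichol_given_diabetes
        bp_elev = htn & (rng.random(n) < bp_elev_rate)
        chol_elev = hichol & (rng.random(n) < chol_elev_rate)
        a1c_poor = diagnosed & (rng.random(n) < 1.0 - st.a1c_control)
        undiag_a1c_detect = undiag & (rng.random(n) < config.undiag_frac_a1c)

        # biomarkers conditional on status
        a1c = np.empty(n)
        fpg = np.empty(n)
        for mask, a1c_par, fpg_par in (
            (diabetes == "none", bm.a1c_none, bm.fpg_none),
            (undiag & undiag_a1c_detect, bm.a1c_undiag_detect, bm.fpg_elevated),
            (undiag & ~undiag_a1c_detect, bm.a1c_undiag_latent, bm.fpg_elevated),
            (diagnosed & ~a1c_poor, bm.a1c_diag_control, bm.fpg_diag),
            (diagnosed & a1c_poor, bm.a1c_diag_poor, bm.fpg_diag),
        ):
            k = int(mask.sum())
            if k:
                a1c[mask] = _draw_trunc(rng, a1c_par, k)
                fpg[mask] = _draw_trunc(rng, fpg_par, k)

        sbp = np.where(bp_elev, _draw_trunc(rng, bm.sbp_elevated, n),
                       _draw_trunc(rng, bm.sbp_control, n))
        dbp = _draw_trunc(rng, bm.dbp_control, n)
        hdl = _draw_trunc(rng, bm.hdl, n)
        nonhdl = np.where(chol_elev, _draw_trunc(rng, bm.nonhdl_elevated, n),
                          _draw_trunc(rng, bm.nonhdl_control, n))
        tc = hdl + nonhdl

        frames.append(pd.DataFrame({
            "person_id": [f"{state}-{i:06d}" for i in range(n)],
            "state": state,
            "county": np.array(counties, dtype=object)[county_of],
            "age": age,
            "age_band": np.array(AGE_BAND_LABELS, dtype=object)[band_idx],
            "sex": sex,
            "race_eth": race,
            "insurance": insurance,
            "education": education,
            "health_status": health,
            "pregnant": pregnant,
            "office_visit": office_visit,
            "diabetes": diabetes,
            "undiag_a1c_detect": undiag_a1c_detect,
            "htn": htn,
            "hichol": hichol,
            "a1c_poor": a1c_poor,
            "bp_elev": bp_elev,
            "chol_elev": chol_elev,
            "a1c": np.round(a1c, 2),
            "fpg": np.round(fpg, 1),
            "sbp": np.round(sbp, 0),
            "dbp": np.round(dbp, 0),
            "tc": np.round(tc, 1),
            "hdl": np.round(hdl, 1),
        }))
    return pd.concat(frames, ignore_index=True)


def _rand_dates(rng: np.random.Generator, start: str, end: str, size: int) -> np.ndarray:
    s, e = np.datetime64(start), np.datetime64(end)
    days = int((e - s) / np.timedelta64(1, "D"))
    return (s + rng.integers(0, days + 1, size).astype("timedelta64[D]")).astype(str)


def build_ehr_tables(census: pd.DataFrame, config: TruthConfig,
                     rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Derive the six-table EHR extract from the census population.

    Inclusion requires an office visit and residence in a covered county;
    inclusion probability is the county's configured network coverage, so the
    extract clusters geographically. Diagnoses and prescriptions are recorded
    with sensitivity below one; labs and vitals appear with the configured
    measurement probabilities (A1c and lipids far less often than vitals, and
    more often for diagnosed diabetics).
    """
    ep = config.ehr
    parts = []
    for state, st in config.states.items():
        cov = np.asarray(st.county_coverage if st.county_coverage is not None
                         else _default_coverage(st.n_counties))
        sub = census[census["state"] == state]
        cidx = sub["county"].str.slice(-2).astype(int).to_numpy()
        p_inc = np.where(sub["office_visit"].to_numpy(), cov[cidx], 0.0)
        parts.append(sub[rng.random(len(sub)) < p_inc])
    pop = pd.concat(parts, ignore_index=True)
    n = len(pop)

    demographics = pop[["person_id", "age", "sex", "county", "state"]].copy()
    providers = (pop[["county", "state"]].drop_duplicates().reset_index(drop=True))
    providers.insert(0, "provider_id", [f"prov-{i:04d}" for i in range(len(providers))])
    prov_of_county = dict(zip(providers["county"], providers["provider_id"]))

    # visits (1-4 per person, all within the index year) carry vitals
    n_vis = 1 + rng.poisson(1.2, n)
    vis_pid = np.repeat(pop["person_id"].to_numpy(), n_vis)
    vis_county = np.repeat(pop["county"].to_numpy(), n_vis)
    visits = pd.DataFrame({
        "person_id": vis_pid,
        "visit_date": _rand_dates(rng, "2013-01-01", "2013-12-31", len(vis_pid)),
        "provider_id": [prov_of_county[c] for c in vis_county],
        "sbp": np.nan, "dbp": np.nan,
    })
    bp_measured = rng.random(n) < ep.p_bp
    bp_rows = np.repeat(bp_measured, n_vis)
    k = int(bp_rows.sum())
    elev = np.repeat(pop["bp_elev"].to_numpy(), n_vis)[bp_rows]
    bm = config.biomarkers
    sbp = np.where(elev, _draw_trunc(rng, bm.sbp_elevated, k), _draw_trunc(rng, bm.sbp_control, k))
    visits.loc[bp_rows, "sbp"] = np.round(sbp, 0)
    visits.loc[bp_rows, "dbp"] = np.round(_draw_trunc(rng, bm.dbp_control, k), 0)
    # guarantee >= 2 readings for measured persons (single visits get a second row)
    single = bp_measured & (n_vis < 2)
    if single.any():
        extra = visits[visits["person_id"].isin(pop.loc[single, "person_id"])].copy()
        extra = extra[extra["sbp"].notna()].drop_duplicates("person_id")
        extra["visit_date"] = _rand_dates(rng, "2013-01-01", "2013-12-31", len(extra))
        visits = pd.concat([visits, extra], ignore_index=True)

    diagnosed = (pop["diabetes"] == "diagnosed").to_numpy()
    dx_rows = []
    for domain, case in (("diabetes", diagnosed),
                         ("hypertension", pop["htn"].to_numpy()),
                         ("cholesterol", pop["hichol"].to_numpy())):
        rec = case & (rng.random(n) < ep.event_sensitivity)
        pids = pop.loc[rec, "person_id"]
        dx_rows.append(pd.DataFrame({
            "person_id": pids.to_numpy(),
            "domain": domain,
            "date": _rand_dates(rng, "2010-01-01", "2013-12-31", len(pids)),
        }))
    diagnoses = pd.concat(dx_rows, ignore_index=True)

    rx_rows = []
    for domain, case, p in (("diabetes", diagnosed, ep.p_rx_given_diagnosed),
                            ("hypertension", pop["htn"].to_numpy(), _P_RX_HTN),
                            ("cholesterol", pop["hichol"].to_numpy(), _P_RX_CHOL)):
        rec = case & (rng.random(n) < p)
        pids = pop.loc[rec, "person_id"]
        rx_rows.append(pd.DataFrame({
            "person_id": pids.to_numpy(),
            "domain": domain,
            "date": _rand_dates(rng, "2010-01-01", "2013-12-31", len(pids)),
        }))
    prescriptions = pd.concat(rx_rows, ignore_index=True)

    lab_rows = []
    a1c_meas = rng.random(n) < np.where(diagnosed, ep.p_a1c_diagnosed, ep.p_a1c_other)
    pids = pop.loc[a1c_meas, "person_id"]
    lab_rows.append(pd.DataFrame({
        "person_id": pids.to_numpy(), "analyte": "a1c",
        "value": pop.loc[a1c_meas, "a1c"].to_numpy(),
        "date": _rand_dates(rng, "2012-01-01", "2013-12-31", len(pids)),
    }))
    p_chol = np.where(diagnosed,
                      np.where(a1c_meas, ep.p_chol_given_a1c_diagnosed,
                               ep.p_chol_given_noa1c_diagnosed),
                      ep.p_chol_other)
    chol_meas = rng.random(n) < p_chol
    pids = pop.loc[chol_meas, "person_id"]
    dates = _rand_dates(rng, "2012-01-01", "2013-12-31", len(pids))
    for analyte, col in (("total_cholesterol", "tc"), ("hdl_c", "hdl")):
        lab_rows.append(pd.DataFrame({
            "person_id": pids.to_numpy(), "analyte": analyte,
            "value": pop.loc[chol_meas, col].to_numpy(), "date": dates,
        }))
    labs = pd.concat(lab_rows, ignore_index=True)

    return {"demographics": demographics, "visits": visits, "diagnoses": diagnoses,
            "labs": labs, "prescriptions": prescriptions, "providers": providers}


def _default_coverage(n_counties: int) -> np.ndarray:
    """Half the counties covered at declining rates, the rest uncovered."""
    cov = np.zeros(n_counties)
    k = max(1, n_counties // 2)
    cov[:k] = np.linspace(0.5, 0.2, k)
    return cov


_SURVEY_COLS = ["person_id", "age", "age_band", "sex", "race_eth", "insurance",
                "education", "health_status", "pregnant", "office_visit"]


def _survey_biomarkers(sub: pd.DataFrame, config: TruthConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Attach exam-style measurements and self-reports to sampled persons."""
    out = sub[_SURVEY_COLS].copy()
    n = len(sub)
    sens = config.self_report_sensitivity
    out["self_report_diabetes"] = ((sub["diabetes"] == "diagnosed")
                                   & (rng.random(n) < sens)).to_numpy()
    out["self_report_htn"] = (sub["htn"] & (rng.random(n) < sens)).to_numpy()
    out["self_report_chol"] = (sub["hichol"] & (rng.random(n) < sens)).to_numpy()
    out["a1c"] = sub["a1c"].to_numpy()
    bm = config.biomarkers
    elev = sub["bp_elev"].to_numpy()
    for i in (1, 2):
        sbp = np.where(elev, _draw_trunc(rng, bm.sbp_elevated, n),
                       _draw_trunc(rng, bm.sbp_control, n))
        out[f"sbp{i}"] = np.round(sbp, 0)
        out[f"dbp{i}"] = np.round(_draw_trunc(rng, bm.dbp_control, n), 0)
    out["tc"] = sub["tc"].to_numpy()
    out["hdl"] = sub["hdl"].to_numpy()
    return out


def build_national_survey(census: pd.DataFrame, config: TruthConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Stratified two-stage national sample: states are strata, counties are
    PSUs drawn with replacement, persons subsampled within each drawn PSU.
    Fasting glucose is measured on a random half of respondents only."""
    sd = config.survey
    rows = []
    for si, (state, st) in enumerate(config.states.items()):
        sub = census[census["state"] == state]
        counties = sorted(sub["county"].unique())
        m = sd.national_psus_per_stratum
        draws = rng.choice(len(counties), size=m, replace=True)
        for pi, ci in enumerate(draws):
            pool = sub[sub["county"] == counties[ci]]
            take = min(sd.national_persons_per_psu, len(pool))
            pick = pool.iloc[rng.choice(len(pool), size=take, replace=False)]
            rec = _survey_biomarkers(pick, config, rng)
            rec["stratum"] = f"ns{si:02d}"
            rec["psu"] = f"ns{si:02d}-p{pi:02d}"
            rec["base_weight"] = (len(counties) / m) * (len(pool) / take)
            rows.append(rec)
    out = pd.concat(rows, ignore_index=True)
    census_ids = out["person_id"].to_numpy()
    out["person_id"] = [f"natl-{i:06d}" for i in range(len(out))]
    half = rng.permutation(len(out)) < len(out) // 2
    out["fpg_subsample"] = half
    # fpg of the underlying census person, revealed for the half-sample only
    fpg_vals = census.set_index("person_id")["fpg"].reindex(census_ids).to_numpy()
    fpg = np.full(len(out), np.nan)
    fpg[half] = fpg_vals[half]
    out["fpg"] = fpg
    return out


def build_panel_survey(census: pd.DataFrame, config: TruthConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """State-identified simple random sample of the 50+ population; biomarkers
    measured on everyone except fasting glucose (never collected)."""
    sd = config.survey
    rows = []
    for state in config.states:
        sub = census[census["state"] == state]
        n = sd.panel_n_per_state.get(state, sd.panel_default_n)
        n = min(n, len(sub))
        pick = sub.iloc[rng.choice(len(sub), size=n, replace=False)]
        rec = _survey_biomarkers(pick, config, rng)
        rec["state"] = state
        rec["stratum"] = f"pn-{state}"
        rec["psu"] = [f"pn-{state}-{i:05d}" for i in range(n)]
        rec["base_weight"] = len(sub) / n
        rows.append(rec)
    out = pd.concat(rows, ignore_index=True)
    out["person_id"] = [f"panel-{i:06d}" for i in range(len(out))]
    return out


def generate_margins(census: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Census-style control totals from the simulated population.

    Returns county age x sex counts (post-stratification targets), state
    age x sex counts restricted to persons with an office visit in the past
    year (the EHR step-2 raking target), and state marginal counts of the
    demographic and health-status adjustment variables.
    """
    county = (census.groupby(["state", "county", "age_band", "sex"], observed=True)
              .size().rename("target").reset_index())
    ov = census[census["office_visit"]]
    state_ov = (ov.groupby(["state", "age_band", "sex"], observed=True)
                .size().rename("target").reset_index())
    marg = []
    for var in ("age_band", "sex", "race_eth", "insurance", "education", "health_status"):
        g = census.groupby(["state", var], observed=True).size().rename("target").reset_index()
        g = g.rename(columns={var: "cell"})
        g.insert(1, "variable", var)
        marg.append(g)
    state_margins = pd.concat(marg, ignore_index=True)
    return {"county_age_sex": county, "state_age_sex_officevisit": state_ov,
            "state_margins": state_margins}


def build_reference_samples(census: pd.DataFrame, config: TruthConfig,
                            rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Per-state covariate reference samples drawn from the census, used by
    the propensity step as the target-population exemplar."""
    out = {}
    cols = ["age", "age_band", "sex", "race_eth", "insurance", "education", "health_status"]
    for state in config.states:
        sub = census[census["state"] == state]
        n = min(config.survey.reference_n_per_state, len(sub))
        pick = sub.iloc[rng.choice(len(sub), size=n, replace=False)]
        out[state] = pick[cols].reset_index(drop=True)
    return out


def compute_truth(census: pd.DataFrame, config: TruthConfig) -> pd.DataFrame:
    """Realized (finite-population) truth per state among the eligible
    population: age 50+, office visit in the past year, not pregnant."""
    rows = []
    for state, st in config.states.items():
        el = census[(census["state"] == state) & census["office_visit"]
                    & ~census["pregnant"]]
        diab = el[el["diabetes"] != "none"]
        diag = el[el["diabetes"] == "diagnosed"]
        rows.append({
            "state": state,
            "config_diagnosed": st.diagnosed,
            "config_undiagnosed": st.undiagnosed,
            "diagnosed": (el["diabetes"] == "diagnosed").mean(),
            "undiagnosed": (el["diabetes"] == "undiagnosed").mean(),
            "htn_given_diabetes": diab["htn"].mean(),
            "hichol_given_diabetes": diab["hichol"].mean(),
            "both_given_diabetes": (diab["htn"] & diab["hichol"]).mean(),
            "neither_given_diabetes": (~diab["htn"] & ~diab["hichol"]).mean(),
            "a1c_control": 1.0 - diag["a1c_poor"].mean(),
            "bp_control": 1.0 - diag["bp_elev"].mean(),
            "chol_control": 1.0 - diag["chol_elev"].mean(),
            "n_eligible": len(el),
        })
    return pd.DataFrame(rows)


def generate_bundle(config: TruthConfig, seed: int | None = None) -> SyntheticBundle:
    """Generate the full synthetic study: population, three sources, margins,
    reference samples and the realized truth table.

    Deterministic: the same (config, seed) always yields identical tables.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    census = simulate_census(config, rng)
    ehr = build_ehr_tables(census, config, rng)
    natl = build_national_survey(census, config, rng)
    panel = build_panel_survey(census, config, rng)
    margins = generate_margins(census)
    reference = build_reference_samples(census, config, rng)
    truth = compute_truth(census, config)
    manifest = {"seed": seed, "states": list(config.states),
                "n_census": int(len(census)), "n_ehr": int(len(ehr["demographics"])),
                "n_national": int(len(natl)), "n_panel": int(len(panel))}
    return SyntheticBundle(ehr_tables=ehr, national_survey=natl, panel_survey=panel,
                           margins=margins, reference=reference, truth=truth,
                           census=census, config=config, seed=seed, manifest=manifest)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path,
                 include_census: bool = False) -> None:
    """Write every table as UTF-8 CSV plus a manifest JSON."""
    out = Path(outdir)
    (out / "ehr").mkdir(parents=True, exist_ok=True)
    (out / "margins").mkdir(exist_ok=True)
    (out / "reference").mkdir(exist_ok=True)
    for name, df in bundle.ehr_tables.items():
        df.to_csv(out / "ehr" / f"{name}.csv", index=False)
    bundle.national_survey.to_csv(out / "national_survey.csv", index=False)
    bundle.panel_survey.to_csv(out / "panel_survey.csv", index=False)
    for name, df in bundle.margins.items():
        df.to_csv(out / "margins" / f"{name}.csv", index=False)
    for state, df in bundle.reference.items():
        df.to_csv(out / "reference" / f"{state}.csv", index=False)
    bundle.truth.to_csv(out / "truth.csv", index=False)
    if include_census:
        bundle.census.to_csv(out / "census.csv", index=False)
    from dataclasses import asdict
    manifest = dict(bundle.manifest)
    manifest["config"] = asdict(bundle.config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def simulate_survey_replicate(prevalence: float, n_strata: int = 25,
                              psus_per_stratum: int = 4, persons_per_psu: int = 50,
                              cluster_jitter: float = 0.03,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One stratified cluster-sample replicate from a superpopulation with a
    known case prevalence, for calibration studies of the design-based
    variance machinery.

    Cluster-level prevalences are jittered symmetrically around the truth
    (uniform on +/- ``cluster_jitter``) so the marginal prevalence stays
    exactly at ``prevalence`` while a genuine design effect is present.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo = max(0.0, prevalence - cluster_jitter)
    hi = min(1.0, prevalence + cluster_jitter)
    if not np.isclose(hi - prevalence, prevalence - lo):
        raise ValueError("cluster_jitter must keep the prevalence band inside (0, 1)")
    n_psu = n_strata * psus_per_stratum
    p_c = rng.uniform(lo, hi, n_psu)
    y = rng.random((n_psu, persons_per_psu)) < p_c[:, None]
    return pd.DataFrame({
        "y": y.ravel().astype(float),
        "weight": 1.0,
        "stratum": np.repeat([f"s{i:03d}" for i in range(n_strata)],
                             psus_per_stratum * persons_per_psu),
        "psu": np.repeat([f"p{i:04d}" for i in range(n_psu)], persons_per_psu),
    })
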