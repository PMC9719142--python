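"""Configuration objects for the surveillance pipeline.

Three groups of settings:

* :class:`TruthConfig` — the ground-truth parameterization of the synthetic
  population (per-state prevalences, biomarker distributions, EHR coverage
  and measurement probabilities, survey design sizes).
* :class:`RuleWindows` / :class:`CutPoints` — the clinical case-definition
  windows and thresholds.
* :class:`RunConfig` — everything a full pipeline run needs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Any

import yaml

AGE_BANDS: tuple[tuple[int, int], ...] = ((50, 59), (60, 69), (70, 79), (80, 99))
AGE_BAND_LABELS: tuple[str, ...] = ("50-59", "60-69", "70-79", "80+")
SEXES: tuple[str, ...] = ("female", "male")

RACE_LEVELS = ("white", "black", "hispanic", "other")
INSURANCE_LEVELS = ("private", "medicare", "medicaid", "none")
EDUCATION_LEVELS = ("lt_hs", "hs", "some_college", "college")
HEALTH_LEVELS = ("excellent_vg", "good", "fair_poor")


def age_band(age: int | float) -> str:
    """Map an age in years to its surveillance age band (50+ only)."""
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo <= age <= hi:
            return label
    return AGE_BAND_LABELS[-1] if age > AGE_BANDS[-1][1] else ""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class StateTruth:
    """Ground truth for one state.

    ``county_coverage`` gives, per county, the probability that a resident
    with an office visit appears in the EHR network (0 = county uncovered).
    ``county_age_tilt`` skews a county's age distribution: positive values
    shift mass toward younger bands, so coverage correlated with tilt yields
    a demographically biased EHR sample.
    """

    diagnosed: float = 0.20
    undiagnosed: float = 0.035
    htn_given_diabetes: float = 0.78
    hichol_given_diabetes: float = 0.68
    htn_background: float = 0.45
    hichol_background: float = 0.40
    a1c_control: float = 0.87
    bp_control: float = 0.70
    chol_control: float = 0.57
    n_counties: int = 8
    population: int = 40_000
    county_coverage: tuple[float, ...] | None = None
    county_age_tilt: tuple[float, ...] | None = None

    def validate(self, state: str) -> None:
        for name in (
            "diagnosed",
            "undiagnosed",
            "htn_given_diabetes",
            "hichol_given_diabetes",
            "htn_background",
            "hichol_background",
            "a1c_control",
            "bp_control",
            "chol_control",
        ):
            _check_prob(f"{state}.{name}", getattr(self, name))
        if self.diagnosed + self.undiagnosed > 1.0:
            raise ValueError(
                f"{state}: diagnosed + undiagnosed exceeds 1 "
                f"({self.diagnosed} + {self.undiagnosed})"
            )
        if self.population <= 0:
            raise ValueError(f"{state}.population must be positive")
        if self.n_counties <= 0:
            raise ValueError(f"{state}.n_counties must be positive")
        for attr in ("county_coverage", "county_age_tilt"):
            vals = getattr(self, attr)
            if vals is not None and len(vals) != self.n_counties:
                raise ValueError(
                    f"{state}.{attr} must have length n_counties={self.n_counties}"
                )
        if self.county_coverage is not None:
            for i, c in enumerate(self.county_coverage):
                _check_prob(f"{state}.county_coverage[{i}]", c)
        # BP/cholesterol control is only possible to fail among true cases,
        # so the implied within-case control rate must be a probability.
        for ctrl, comorb, name in (
            (self.bp_control, self.htn_given_diabetes, "bp_control"),
            (self.chol_control, self.hichol_given_diabetes, "chol_control"),
        ):
            implied = (ctrl - (1.0 - comorb)) / comorb if comorb > 0 else 1.0
            if not (0.0 <= implied <= 1.0):
                raise ValueError(
                    f"{state}.{name}={ctrl} incompatible with comorbidity "
                    f"prevalence {comorb} (implied within-case control {implied:.3f})"
                )


@dataclass
class BiomarkerParams:
    """Normal (mean, sd, lower, upper) draws conditional on disease status.

    Truncation keeps each group on the correct side of the diagnostic and
    control cut points, so a fully measured population classifies exactly
    back to the generating truth.
    """

    a1c_none: tuple[float, float, float, float] = (5.4, 0.35, 3.8, 6.49)
    a1c_undiag_detect: tuple[float, float, float, float] = (7.0, 0.5, 6.5, 10.0)
    a1c_undiag_latent: tuple[float, float, float, float] = (6.0, 0.25, 5.0, 6.49)
    a1c_diag_control: tuple[float, float, float, float] = (7.2, 0.8, 4.5, 8.99)
    a1c_diag_poor: tuple[float, float, float, float] = (10.2, 1.0, 9.0, 16.0)
    fpg_none: tuple[float, float, float, float] = (95.0, 10.0, 50.0, 125.9)
    fpg_elevated: tuple[float, float, float, float] = (150.0, 18.0, 126.0, 300.0)
    fpg_diag: tuple[float, float, float, float] = (145.0, 30.0, 70.0, 350.0)
    sbp_control: tuple[float, float, float, float] = (124.0, 8.0, 85.0, 139.9)
    dbp_control: tuple[float, float, float, float] = (76.0, 6.0, 45.0, 89.9)
    sbp_elevated: tuple[float, float, float, float] = (152.0, 9.0, 140.0, 220.0)
    hdl: tuple[float, float, float, float] = (50.0, 12.0, 20.0, 110.0)
    nonhdl_control: tuple[float, float, float, float] = (105.0, 15.0, 40.0, 129.9)
    nonhdl_elevated: tuple[float, float, float, float] = (155.0, 18.0, 130.0, 280.0)


@dataclass
class EhrParams:
    """EHR observation process: what gets recorded, and for whom."""

    # probability a lab panel / vitals are present in the control window;
    # among diagnosed diabetics the lipid panel is strongly coupled to A1c
    # testing (the same clinical encounter orders both), so its probability
    # is specified conditionally on A1c measurement
    p_a1c_diagnosed: float = 0.52
    p_a1c_other: float = 0.15
    p_bp: float = 0.96
    p_chol_given_a1c_diagnosed: float = 0.82
    p_chol_given_noa1c_diagnosed: float = 0.07
    p_chol_other: float = 0.40
    # probability a true case has a recorded diagnosis event
    event_sensitivity: float = 0.95
    # probability a diagnosed diabetic has an anti-diabetic prescription row
    p_rx_given_diagnosed: float = 0.80

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(f"ehr.{f.name}", getattr(self, f.name))


@dataclass
class SurveyDesign:
    """Design sizes for the two survey sources.

    The national survey is a stratified two-stage sample (states are strata,
    counties are PSUs drawn with replacement). The panel survey is a
    within-state simple random sample of the 50+ population.
    """

    national_psus_per_stratum: int = 8
    national_persons_per_psu: int = 150
    panel_n_per_state: dict[str, int] = field(
        default_factory=lambda: {"CA": 900, "FL": 700})
    panel_default_n: int = 300
    reference_n_per_state: int = 2000

    def validate(self) -> None:
        if self.national_psus_per_stratum < 2:
            raise ValueError("national_psus_per_stratum must be >= 2")
        if self.national_persons_per_psu <= 0:
            raise ValueError("national_persons_per_psu must be positive")
        for k, v in self.panel_n_per_state.items():
            if v <= 0:
                raise ValueError(f"panel_n_per_state[{k}] must be positive")


DEFAULT_STATES = ("AL", "CA", "FL", "LA", "MA")
DEFAULT_DIVISIONS = {"AL": "south", "LA": "south", "FL": "south", "CA": "west", "MA": "northeast"}


@dataclass
class TruthConfig:
    """Full ground-truth parameterization of the synthetic study."""

    states: dict[str, StateTruth] = field(
        default_factory=lambda: {
            "AL": StateTruth(diagnosed=0.24, undiagnosed=0.035),
            "CA": StateTruth(diagnosed=0.18, undiagnosed=0.045),
            "FL": StateTruth(diagnosed=0.20, undiagnosed=0.035),
            "LA": StateTruth(diagnosed=0.22, undiagnosed=0.035),
            "MA": StateTruth(diagnosed=0.17, undiagnosed=0.030),
        }
    )
    divisions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIVISIONS))
    biomarkers: BiomarkerParams = field(default_factory=BiomarkerParams)
    ehr: EhrParams = field(default_factory=EhrParams)
    survey: SurveyDesign = field(default_factory=SurveyDesign)
    # fraction of undiagnosed cases whose A1c (not only FPG) is diagnostic
    undiag_frac_a1c: float = 0.6
    # relative risk of diabetes by age band; normalized against the realized
    # age distribution so the population-average prevalence hits the target
    age_rr: tuple[float, ...] = (0.70, 0.95, 1.25, 1.45)
    office_visit_rate: tuple[float, ...] = (0.80, 0.85, 0.88, 0.90)
    pregnancy_rate: float = 0.0
    pregnancy_age_cap: int = 55
    self_report_sensitivity: float = 1.0
    seed: int = 20220
    # between-PSU heterogeneity of diabetes risk (log-odds sd) so the
    # cluster design carries real design effects
    cluster_sd: float = 0.15

    def validate(self) -> None:
        if not self.states:
            raise ValueError("states must be non-empty")
        for name, st in self.states.items():
            st.validate(name)
            if name not in self.divisions:
                raise ValueError(f"state {name} missing from divisions map")
        self.ehr.validate()
        self.survey.validate()
        _check_prob("undiag_frac_a1c", self.undiag_frac_a1c)
        _check_prob("pregnancy_rate", self.pregnancy_rate)
        _check_prob("self_report_sensitivity", self.self_report_sensitivity)
        if len(self.age_rr) != len(AGE_BANDS):
            raise ValueError("age_rr must have one entry per age band")
        if len(self.office_visit_rate) != len(AGE_BANDS):
            raise ValueError("office_visit_rate must have one entry per age band")

    @classmethod
    def small(cls, n_states: int = 2, population: int = 8000) -> "TruthConfig":
        """A scaled-down configuration for demos and fast tests."""
        cfg = cls()
        keep = list(cfg.states)[:n_states]
        cfg.states = {k: cfg.states[k] for k in keep}
        cfg.divisions = {k: cfg.divisions[k] for k in keep}
        for st in cfg.states.values():
            st.population = population
            st.n_counties = 4
        cfg.survey.national_psus_per_stratum = 4
        cfg.survey.national_persons_per_psu = 100
        cfg.survey.reference_n_per_state = 800
        return cfg


@dataclass
class RuleWindows:
    """Calendar windows for case finding and for control assessment."""

    case_start: date = date(2010, 1, 1)
    case_end: date = date(2013, 12, 31)
    control_start: date = date(2012, 1, 1)
    control_end: date = date(2013, 12, 31)

    def validate(self) -> None:
        if not (self.case_start <= self.control_start <= self.control_end <= self.case_end):
            raise ValueError("control interval must be contained in the case-finding interval")


@dataclass(frozen=True)
class CutPoints:
    """Clinical thresholds. Diagnostic cuts are inclusive (>=); control
    targets are exclusive (<)."""

    a1c_diabetes: float = 6.5
    fpg_diabetes: float = 126.0
    sbp_elevated: float = 140.0
    dbp_elevated: float = 90.0
    nonhdl_high: float = 130.0
    a1c_poor_control: float = 9.0


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    truth: TruthConfig = field(default_factory=TruthConfig)
    windows: RuleWindows = field(default_factory=RuleWindows)
    cutpoints: CutPoints = field(default_factory=CutPoints)
    index_date: date = date(2013, 12, 31)
    rake_tol: float = 1e-8
    rake_max_iter: int = 500
    trim_factor: float = 20.0
    panel_threshold: int = 500
    imputation: bool = True
    n_imputations: int = 10
    imputation_predictors: tuple[str, ...] = ("a1c", "age", "sex")
    alpha: float = 0.01
    seed: int = 1
    output_dir: str = "statesurv_run"

    def validate(self) -> None:
        self.truth.validate()
        self.windows.validate()
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.rake_tol <= 0 or self.rake_max_iter <= 0:
            raise ValueError("rake_tol and rake_max_iter must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        cfg = cls()
        truth_raw = raw.pop("truth", None)
        if truth_raw:
            states_raw = truth_raw.pop("states", None)
            if states_raw:
                cfg.truth.states = {
                    k: StateTruth(**{kk: tuple(vv) if isinstance(vv, list) else vv
                                     for kk, vv in v.items()})
                    for k, v in states_raw.items()
                }
            for k, v in truth_raw.items():
                if k in ("biomarkers", "ehr", "survey"):
                    sub = getattr(cfg.truth, k)
                    for kk, vv in v.items():
                        setattr(sub, kk, tuple(vv) if isinstance(vv, list) else vv)
                else:
                    setattr(cfg.truth, k, tuple(v) if isinstance(v, list) else v)
        for k, v in raw.items():
            if k in ("windows",):
                for kk, vv in v.items():
                    setattr(cfg.windows, kk, date.fromisoformat(vv))
            elif k == "cutpoints":
                cfg.cutpoints = CutPoints(**v)
            elif k == "index_date":
                cfg.index_date = date.fromisoformat(v)
            elif k == "imputation_predictors":
                cfg.imputation_predictors = tuple(v)
            else:
                setattr(cfg, k, v)
        cfg.validate()
        return cfg
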