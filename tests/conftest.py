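import numpy as np
import pandas as pd
import pytest

from statesurv import TruthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config() -> TruthConfig:
    return TruthConfig.small(2, 8000)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config, seed=11)


@pytest.fixture(scope="session")
def exact_bundle():
    """Bundle where recording and measurement are perfect, so classification
    must reproduce the generating truth exactly."""
    cfg = TruthConfig.small(1, 6000)
    cfg.ehr.event_sensitivity = 1.0
    cfg.ehr.p_a1c_diagnosed = 1.0
    cfg.ehr.p_a1c_other = 1.0
    cfg.ehr.p_bp = 1.0
    cfg.ehr.p_chol_given_a1c_diagnosed = 1.0
    cfg.ehr.p_chol_given_noa1c_diagnosed = 1.0
    cfg.ehr.p_chol_other = 1.0
    cfg.undiag_frac_a1c = 1.0
    return generate_bundle(cfg, seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def tiny_ehr_tables() -> dict[str, pd.DataFrame]:
    """Hand-built six-table EHR fixture: 3 persons, one with 3 visits and
    2 labs, one stale (no recent visit), one with an orphan lab row."""
    demographics = pd.DataFrame({
        "person_id": ["a", "b", "c"],
        "age": [62, 55, 71],
        "sex": ["female", "male", "female"],
        "county": ["XX-c00", "XX-c00", "XX-c01"],
        "state": ["XX", "XX", "XX"],
    })
    visits = pd.DataFrame({
        "person_id": ["a", "a", "a", "b", "c"],
        "visit_date": ["2013-02-01", "2013-06-15", "2013-11-30",
                       "2011-05-01", "2013-08-08"],
        "provider_id": ["p1", "p1", "p1", "p1", "p2"],
        "sbp": [150.0, np.nan, 143.0, np.nan, 120.0],
        "dbp": [85.0, np.nan, 88.0, np.nan, 70.0],
    })
    labs = pd.DataFrame({
        "person_id": ["a", "a", "zz-orphan"],
        "analyte": ["a1c", "total_cholesterol", "a1c"],
        "value": [7.1, 210.0, 9.9],
        "date": ["2013-03-01", "2013-03-01", "2013-01-01"],
    })
    diagnoses = pd.DataFrame({
        "person_id": ["a"], "domain": ["diabetes"], "date": ["2012-01-15"],
    })
    prescriptions = pd.DataFrame(
        {"person_id": [], "domain": [], "date": []}).astype(
        {"person_id": object, "domain": object, "date": object})
    providers = pd.DataFrame({
        "provider_id": ["p1", "p2"], "county": ["XX-c00", "XX-c01"],
        "state": ["XX", "XX"],
    })
    return {"demographics": demographics, "visits": visits, "labs": labs,
            "diagnoses": diagnoses, "prescriptions": prescriptions,
            "providers": providers}
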