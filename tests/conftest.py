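import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mtpcost as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    cfg = m.default_params()
    cfg.n_subjects = 60
    cfg.seed = 123
    return cfg


@pytest.fixture(scope="session")
def small_panel(small_config):
    return m.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_design(small_panel):
    return m.build_design(small_panel)


@pytest.fixture(scope="session")
def ref_fit():
    return m.reference_fit()


@pytest.fixture(scope="session")
def fitted_small(small_design):
    """One real (small) maximum-likelihood fit shared across tests."""
    return m.fit(small_design, quad=m.QuadratureSpec(3),
                 options=m.FitOptions(max_outer=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def tiny_claims():
    """Hand-built claims stream with known diagnosis months."""
    rows = [
        # washout-period case: first N18 in 2003-05
        ("w1", "2003-05", 50.0, "N18.3"),
        ("w1", "2010-01", 10.0, "I10"),
        # incident case diagnosed 2010-07, with a claim two months before
        ("a1", "2010-05", 120.0, "E11"),
        ("a1", "2010-07", 80.0, "N18.9;I10"),
        ("a1", "2010-08", 40.0, "N18.9"),
        # tail-period case: first N18 in 2018-01
        ("t1", "2018-01", 30.0, "N18.1"),
        # never coded for CKD
        ("x1", "2012-02", 25.0, "J44"),
    ]
    return pd.DataFrame(rows, columns=["subject_id", "month", "cost", "codes"])


@pytest.fixture()
def tiny_attributes():
    return pd.DataFrame({
        "subject_id": ["w1", "a1", "t1", "x1"],
        "parc_value": [0.1, -0.5, 0.2, 0.0],
        "age": [55, 62, 47, 70],
        "sex": ["male", "female", "male", "male"],
        "income": ["middle", "low", "high", "middle"],
        "coverage": ["NHI", "medical_aid", "NHI", "NHI"],
        "cci": [1, 2, 0, 1],
    })
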