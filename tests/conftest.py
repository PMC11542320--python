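import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hetiv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


COMORBS = list(hetiv.SimulationConfig().comorbidity_prevalences)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort under the study-condition defaults."""
    cfg = hetiv.SimulationConfig(n_patients=6000, seed=11)
    cohort, oracle = hetiv.generate_cohort(cfg)
    return cfg, cohort, oracle


@pytest.fixture(scope="session")
def identified_cohort():
    """Cohort from the well-identified verification configuration."""
    cfg = hetiv.simulate.well_identified_config(n_patients=20_000, seed=3)
    cohort, oracle = hetiv.generate_cohort(cfg)
    return cfg, cohort, oracle


@pytest.fixture()
def simple_selection():
    return hetiv.SelectionResult(
        x_forced=["frailty", "chronic_heart_failure"],
        x_selected_d=[],
        x_selected_y=[],
        selected_interactions=[],
    )


def toy_cohort(n=400, seed=0, n_hospitals=8, n_periods=4):
    """Tiny hand-rolled admission frame for unit tests of tabulations."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "hospital_id": rng.integers(0, n_hospitals, n),
            "period": rng.integers(0, n_periods, n),
            "treatment": rng.integers(0, 2, n),
            "outcome": rng.integers(0, 91, n),
            "tto": rng.random(n),
            "age_60_74": rng.integers(0, 2, n),
            "age_75_plus": 0,
            "sex": rng.integers(0, 2, n),
            "frailty": rng.integers(0, 2, n),
            "c1": rng.integers(0, 2, n),
            "c2": rng.integers(0, 2, n),
        }
    )
    df["age_75_plus"] = ((df["age_60_74"] == 0) & (rng.random(n) < 0.3)).astype(int)
    return df
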