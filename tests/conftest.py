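"""Shared fixtures: synthetic cohorts and noiseless linear test data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rmkpredict import GeneratorConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def cohort66(default_config):
    """A full-size synthetic cohort, table only (trajectories not needed)."""
    return generate_cohort(default_config, include_trajectories=False)


@pytest.fixture(scope="session")
def cohort_table(cohort66) -> pd.DataFrame:
    return cohort66.table


def make_linear_table(n: int = 40, seed: int = 0, slope: float = -8.0) -> pd.DataFrame:
    """A cohort table whose discharge scores are an exact linear function
    of the standardized path error toward the body: zero-residual ground
    truth for validation procedures (no snapping applied)."""
    rng = np.random.default_rng(seed)
    mpe_c = rng.uniform(0.005, 0.04, n)
    z = (mpe_c - mpe_c.mean()) / mpe_c.std(ddof=1)
    df = pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(n)],
            "age": rng.normal(65, 12, n),
            "sex": rng.choice(["male", "female"], n),
            "onset_days": rng.uniform(5, 40, n),
            "mi_elbow_t1": rng.choice([0, 9, 14, 19, 25, 33], n).astype(float),
            "mi_shoulder_t1": rng.choice([0, 9, 14, 19, 25, 33], n).astype(float),
            "mi_ul_t1": rng.integers(1, 100, n).astype(float),
            "mpe_a": rng.uniform(0.005, 0.04, n),
            "mpe_c": mpe_c,
            "mpe_d": rng.uniform(0.005, 0.04, n),
            "ms_b": rng.uniform(0.06, 0.3, n),
        }
    )
    for col, intercept in (("mi_elbow_t2", 16.0), ("mi_shoulder_t2", 16.0), ("mi_ul_t2", 50.0)):
        df[col] = intercept + slope * z
    return df


@pytest.fixture()
def linear_table() -> pd.DataFrame:
    return make_linear_table()
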