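"""Shared fixtures: small cohorts generated once per session."""

import numpy as np
import pandas as pd
import pytest

from diabench.cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def t2dm_cohort():
    """Single-centre T2DM cohort at the audited stratum size."""
    cfg = default_config("t2dm", n_centres=1, patients_per_centre=3496)
    return generate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def t1dm_cohort():
    cfg = default_config("t1dm", n_centres=1, patients_per_centre=1174)
    return generate_cohort(cfg, seed=102)


@pytest.fixture(scope="session")
def multi_centre_cohort():
    """Default study-conditions cohort: 49 centres, both diabetes types."""
    return generate_cohort(default_config(), seed=103)


def toy_records(n=200, seed=0, beta=(2.0, 3.0), sd=1.0):
    """Minimal record frame with a single numeric driver (age) of hba1c."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 80, n)
    y = beta[0] + beta[1] * (age / 10.0) + rng.normal(0, sd, n)
    return pd.DataFrame({
        "age": age, "duration": rng.uniform(0, 20, n),
        "sex": rng.choice(["male", "female"], n),
        "country_of_birth": rng.choice(["Australia", "overseas"], n),
        "bmi_category": rng.choice(["healthy", "overweight", "obese"], n),
        "dcsi_category": rng.choice(["0", "1-2", "3-4", "5+"], n),
        "smoking": rng.choice(["never", "ever"], n),
        "on_insulin": rng.random(n) < 0.5,
        "fasting_at_lipids": rng.random(n) < 0.3,
        "hba1c": y,
        "centre_id": "C1",
        "diabetes_type": "t2dm",
    })
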