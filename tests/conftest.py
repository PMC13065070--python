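import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import timeuse_coda as tc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: A realistic weekday geometric-mean profile (minutes, sums to 1440):
#: roughly 15 h sleep+domestic, scarce physical activity and school time out
#: of lessons.
WEEKDAY_GM = pd.Series(
    {
        "sleep": 897.0,
        "physical_activity": 23.0,
        "media": 143.0,
        "school": 50.0,
        "hobbies": 61.0,
        "domestic": 266.0,
    }
)
WEEKEND_GM = pd.Series({"sleep": 852.0, "media": 202.0, "hobbies": 114.0, "domestic": 272.0})


@pytest.fixture(scope="session")
def mapping():
    return tc.ActivityMapping.default()


@pytest.fixture(scope="session")
def weekday_gm():
    return WEEKDAY_GM.copy()


@pytest.fixture(scope="session")
def weekend_gm():
    return WEEKEND_GM.copy()


def analytic_from_cohort(cohort, impute=5.0):
    """Assemble the analytic table directly from generated arrays (no diaries)."""
    comps = cohort.compositions.drop(columns="participant_id")
    replaced = tc.multiplicative_zero_replace(comps, impute=impute)
    return pd.concat(
        [
            replaced,
            cohort.covariates.drop(columns="participant_id"),
            cohort.outcomes[["attainment8"]],
        ],
        axis=1,
    )


@pytest.fixture(scope="session")
def fitted_weekday():
    """A moderately sized noisy weekday fit shared across substitution tests."""
    truth = tc.weekday_truth(seed=424242)
    cohort = tc.generate_cohort(truth, 1000)
    table = analytic_from_cohort(cohort)
    fit = tc.fit_outcome_model(table, truth.basis())
    base = tc.compositional_mean(table[list(truth.parts)])
    return truth, table, fit, base


def random_compositions(rng, n, D, total=1440.0):
    """Strictly positive random compositions closed to *total*."""
    logs = rng.normal(0.0, 1.0, size=(n, D))
    x = np.exp(logs)
    return x * (total / x.sum(axis=1, keepdims=True))
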