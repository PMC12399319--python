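"""Shared fixtures: one mid-sized synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from dunesync import synthetic as syn
from dunesync.climate import monthly_anomalies
from dunesync.demography import build_transitions

CLIMATE_SEED = 11
CENSUS_SEED = 42
VARIABLES = ("prcp", "tmin", "tmean", "tmax", "drought_index")


@pytest.fixture(scope="session")
def climate_table() -> pd.DataFrame:
    return syn.generate_climate(1985, 40, seed=CLIMATE_SEED)


@pytest.fixture(scope="session")
def dataset(climate_table):
    """(census, truth) under the default study conditions."""
    params = syn.default_params()
    return syn.generate_population(params, climate_table, seed=CENSUS_SEED)


@pytest.fixture(scope="session")
def census(dataset):
    return dataset[0]


@pytest.fixture(scope="session")
def truth(dataset):
    return dataset[1]


@pytest.fixture(scope="session")
def transitions(census):
    return build_transitions(census)


@pytest.fixture(scope="session")
def anomalies(climate_table):
    ref = (1985, 2024)
    return {v: monthly_anomalies(climate_table, v, ref) for v in VARIABLES}


@pytest.fixture(scope="session")
def vital_fits(transitions):
    from dunesync.demography import RATES, fit_vital_rate
    return {r: fit_vital_rate(transitions, r) for r in RATES}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
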