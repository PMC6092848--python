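import numpy as np
import pytest
from hypothesis import settings

from apcrate import BandScheme, RateTable, ReferenceSpec
from apcrate.simulate import SimConfig, simulate_events, simulate_miners
from apcrate.cohort import tabulate

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


STUDY_AGE = BandScheme(start=30, width=5, count=8)
STUDY_PERIOD = BandScheme(start=1960, width=5, count=9)


@pytest.fixture(scope="session")
def study_schemes():
    return STUDY_AGE, STUDY_PERIOD


@pytest.fixture(scope="session")
def sim_config():
    """Default-condition synthetic cohort configuration (fixed seed)."""
    return SimConfig(seed=20180814)


@pytest.fixture(scope="session")
def sim_records(sim_config):
    return simulate_events(simulate_miners(sim_config), sim_config)


@pytest.fixture(scope="session")
def sim_table(sim_records, sim_config):
    return tabulate(sim_records, sim_config.age_scheme, sim_config.period_scheme)


def random_rate_table(rng, a=None, p=None, mean_pyears=3000.0, base_log_rate=-6.0):
    """A fully populated random table with enough cases to avoid separation."""
    a = a if a is not None else int(rng.integers(2, 6))
    p = p if p is not None else int(rng.integers(2, 6))
    age = BandScheme(30, 5, a)
    per = BandScheme(1960, 5, p)
    pyears = rng.uniform(0.5 * mean_pyears, 1.5 * mean_pyears, size=(a, p))
    rate = np.exp(rng.normal(base_log_rate, 0.4, size=(a, p)))
    cases = rng.poisson(pyears * rate).astype(float)
    return RateTable(age, per, cases, pyears)


@pytest.fixture
def rng():
    return np.random.default_rng(20180814)
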