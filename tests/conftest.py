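import numpy as np
import pytest

from rocascreen.cohort import CohortConfig, simulate_cohort
from rocascreen.model import HealthyModelParams
from rocascreen.protocol import ProtocolConfig, run_trial


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_trial():
    """A small screened cohort with enough cases for end-to-end checks."""
    config = CohortConfig(n_women=800, years_of_screening=5,
                          annual_incidence=0.01, seed=42)
    cohort = simulate_cohort(config)
    run = run_trial(cohort, ProtocolConfig(), np.random.default_rng(42))
    return cohort, run


@pytest.fixture(scope="session")
def default_healthy():
    return HealthyModelParams()
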