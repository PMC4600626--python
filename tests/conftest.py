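import numpy as np
import pytest

from epiaging.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast 7-type cohort used by several integration tests."""
    return SimulationConfig(
        n_subjects=200, n_probes=120, n_clock_probes=30, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
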