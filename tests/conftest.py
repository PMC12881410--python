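import numpy as np
import pytest

from dagwas.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_individuals=200, n_markers=300, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
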