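import numpy as np
import pytest

import lagrisk as lr


@pytest.fixture(scope="session")
def headline():
    """One headline-scenario realization shared across tests."""
    series, truth = lr.make_headline_scenario(7)
    return series, truth


@pytest.fixture(scope="session")
def env608():
    return lr.simulate_environment(608, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
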