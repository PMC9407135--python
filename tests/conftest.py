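import numpy as np
import pandas as pd
import pytest

from soccertmle.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def small_data(default_config):
    """A modest simulated dataset shared by read-only tests."""
    return simulate(default_config, 2000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """Six-row table with binary W1, solvable by hand via normal equations."""
    return pd.DataFrame(
        {
            "W1": [0, 0, 1, 1, 0, 1],
            "A": [0, 1, 0, 1, 1, 0],
            "Y": [0.20, 0.50, 0.35, 0.80, 0.55, 0.30],
        }
    )
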