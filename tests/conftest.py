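import numpy as np
import pytest

from pm25risk import synthetic


@pytest.fixture(scope="session")
def default_data():
    """Two years of daily records for the default 12-station network."""
    return synthetic.generate_stations(synthetic.SyntheticSpec(n_days=730, seed=0))


@pytest.fixture(scope="session")
def big_data():
    """Long run (n_days=5000) used for correlation-convergence checks."""
    return synthetic.generate_stations(synthetic.SyntheticSpec(n_days=5000, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
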