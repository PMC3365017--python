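import numpy as np
import pytest

from gradecode.encoding import assign_doping_controls, make_encoding_scheme
from gradecode.simulate import SimConfig


@pytest.fixture(scope="session")
def scheme15():
    """Default 15-fraction encoding scheme with symmetric 0.1/0.9 endpoints."""
    return make_encoding_scheme(15, 0.1, 0.9)


@pytest.fixture(scope="session")
def dope15(scheme15):
    return assign_doping_controls(scheme15, controls_per_fraction=4)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(seed=7).noiseless()


@pytest.fixture(scope="session")
def small_config():
    """Cheap cohort for tests exercising mechanics rather than statistics."""
    return SimConfig(seed=7, n_genes=120)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
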