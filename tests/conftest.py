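import numpy as np
import pytest

from catrail import load_default_model
from catrail.network import compile_network


@pytest.fixture(scope="session")
def default_model():
    """Packaged apoptosis network + config, loaded once per session."""
    return load_default_model()


@pytest.fixture(scope="session")
def network(default_model):
    return default_model[0]


@pytest.fixture(scope="session")
def config(default_model):
    return default_model[1]


@pytest.fixture(scope="session")
def compiled(network):
    return compile_network(network)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
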