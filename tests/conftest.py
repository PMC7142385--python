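import numpy as np
import pytest

from heredex import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=20231)


@pytest.fixture(scope="session")
def parent_child_family(default_config):
    return simulate_family(default_config, "parent_child")


@pytest.fixture(scope="session")
def sibling_family(default_config):
    return simulate_family(default_config, "sibling")


@pytest.fixture()
def rng():
    return np.random.default_rng(977)
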