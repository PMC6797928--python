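import pytest
from hypothesis import settings

from methyldelay.simulate import SimulationConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_probes=1500, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size cohort under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))
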