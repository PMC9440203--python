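import pytest

from btcmodel.config import default_config, model_from_config
from btcmodel.simulator import SimulationConfig


@pytest.fixture(scope="session")
def model():
    """The reference BTC model."""
    return model_from_config()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def fast_sim():
    """Short simulation settings for unit tests: 30 s with a 10 s transient."""
    return SimulationConfig(duration=30.0, transient=10.0, seed=7)


@pytest.fixture(scope="session")
def paper_sim():
    """The reference protocol: 120 s at 256 Hz, [20, 120] s epoch."""
    return SimulationConfig(seed=42)
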