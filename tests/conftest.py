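import numpy as np
import pytest

from synapkit import SimulationConfig, StimulationProtocol


@pytest.fixture
def protocol_200ap():
    return StimulationProtocol.train_200ap()


@pytest.fixture
def protocol_200ap_cypher():
    return StimulationProtocol.train_200ap("cypher")


@pytest.fixture
def clean_config():
    """Noiseless, bleach-free pHluorin configuration."""
    return SimulationConfig(tau_endo=30.0, noise_sd_fraction=0.0,
                            amplitude_cv=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
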