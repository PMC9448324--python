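import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eisim.network import (  # noqa: E402
    ExternalInputConfig,
    NetworkConfig,
    NoiseConfig,
    SynapseConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A 12-unit network that integrates in well under a second."""
    return NetworkConfig(n_exc=10, n_inh=2, duration=2.0, seed=7)


@pytest.fixture
def silent_config():
    """No noise, no external drive: the network must stay quiescent."""
    return NetworkConfig(
        n_exc=10,
        n_inh=2,
        duration=1.0,
        seed=7,
        noise=NoiseConfig(ou_sigma=0.0),
        ext_input=ExternalInputConfig(n_sources=0, rate_per_source=0.0),
    )


def single_neuron_config(duration=0.2):
    """Drive-free two-population scaffold for closed-form checks."""
    return NetworkConfig(
        n_exc=1,
        n_inh=1,
        duration=duration,
        seed=0,
        noise=NoiseConfig(ou_sigma=0.0),
        ext_input=ExternalInputConfig(n_sources=0, rate_per_source=0.0),
        synapses=SynapseConfig(lognorm_sigma=0.0),
    )
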