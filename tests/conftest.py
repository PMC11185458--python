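import numpy as np
import pytest

from chunktag import agdesign, synth


@pytest.fixture
def inventory():
    return agdesign.default_inventory()


@pytest.fixture
def timing():
    return agdesign.TimingSpec()


@pytest.fixture
def quiet_params():
    """Noise-free synthesis parameters for deterministic signal checks."""
    return synth.SynthParams(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
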