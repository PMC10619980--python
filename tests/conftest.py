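import numpy as np
import pytest

from dualsleep.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A fast trace configuration for unit tests."""
    return SimConfig(seed=7, T=600, n_active=5, n_silent=5)
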