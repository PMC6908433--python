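import numpy as np
import pytest

from cracm.synthetic import SynapticEventParams


@pytest.fixture
def kernel_params():
    """Fast glutamatergic kernel used across detection/kinetics tests."""
    return SynapticEventParams(tau_rise=0.5, tau_decay=4.0,
                               amplitude_mean=20.0, amplitude_cv=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
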