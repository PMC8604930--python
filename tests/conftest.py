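import numpy as np
import pytest

from arcophys.gating import RateLaw, ResurgentChannelParams
from arcophys.presets import nat_preset, resurgent_channel


@pytest.fixture(scope="session")
def channel() -> ResurgentChannelParams:
    """The shipped (calibrated) resurgent channel parameter set."""
    return resurgent_channel()

@pytest.fixture(scope="session")
def adult_nat():
    return nat_preset("adult_24C")


@pytest.fixture(scope="session")
def juvenile_nat():
    return nat_preset("juvenile_20dph_24C")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_rates():
    """A hand-made, well-behaved rate pair for unit tests."""
    alpha = RateLaw(form="sigmoid", A=0.8, V0=-40.0, K=-8.0)
    beta = RateLaw(form="exponential", A=0.05, V0=-40.0, K=-20.0)
    return alpha, beta
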