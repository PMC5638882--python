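import numpy as np
import pytest

from paradic import InstrumentModel


@pytest.fixture(scope="session")
def inst() -> InstrumentModel:
    """Default virtual instrument."""
    return InstrumentModel()


@pytest.fixture(scope="session")
def quiet_inst() -> InstrumentModel:
    """Noise-free variant of the default instrument."""
    return InstrumentModel(shot_noise=False, read_noise=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
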