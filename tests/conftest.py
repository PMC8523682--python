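import numpy as np
import pytest

from seedconn import BrainMask, Image4D, PhysioTrace, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_mask():
    return BrainMask(np.ones((8, 8, 8), bool))


@pytest.fixture
def small_image(rng):
    """8^3 grid, 40 volumes of white noise at TR 2.8 s."""
    return Image4D(data=rng.normal(size=(8, 8, 8, 40)), tr_s=2.8)


@pytest.fixture
def default_config():
    return SimulationConfig()


@pytest.fixture
def physio_flat():
    """Constant-zero phases: sine columns vanish, cosine columns are one."""
    return PhysioTrace(cardiac_phase=np.zeros(40), resp_phase=np.zeros(40))
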