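import numpy as np
import pytest

from addnet.add_process import AddConfig
from addnet.connectome import generate_surrogate
from addnet.neural_mass import NeuralMassParams


@pytest.fixture(scope="session")
def small_net():
    """Connected 10-node surrogate used by fast simulation tests."""
    return generate_surrogate(10, 0.3, model="erdos_renyi", seed=3)


@pytest.fixture(scope="session")
def brain_net():
    """Default 78-node surrogate (300 edges)."""
    return generate_surrogate(78, 0.10, model="modular", seed=1)


@pytest.fixture()
def fast_params():
    """Short epochs for quick simulation tests."""
    return NeuralMassParams(epoch_len=512, transient_len=256)


@pytest.fixture()
def fast_add():
    """Degeneration config with visible per-epoch effect at short epochs."""
    return AddConfig(kappa=768.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
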