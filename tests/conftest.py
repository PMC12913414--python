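import numpy as np
import pytest

from alignnet.model import ModelConfig
from alignnet.preprocessing import Trial
from alignnet.synthetic import SessionSet, make_session


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale model used for training-behavior tests."""
    return ModelConfig(depth=2, base_width=4, latent_dim=16, proj_hidden=32)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Miniature geometry (8 channels x 16 bins) for fast shape/graph tests."""
    return ModelConfig(n_channels=8, n_time=16, depth=2, base_width=4,
                       latent_dim=8, proj_hidden=8)


@pytest.fixture(scope="session")
def session8():
    return make_session(8, day=0, seed=1)


def light_session(n: int, day: int = 0, n_ch: int = 4, n_t: int = 6) -> SessionSet:
    """Cheap hand-built session (no simulation) for split/protocol tests."""
    rng = np.random.default_rng(day * 1000 + n)
    trials = [Trial(spikes=rng.integers(0, 3, (n_ch, n_t)),
                    behavior=rng.normal(size=(2, n_t)),
                    day=day, direction=k % 8)
              for k in range(n)]
    return SessionSet(trials=trials, day=day)


@pytest.fixture
def tiny_trials():
    rng = np.random.default_rng(7)
    spikes = rng.poisson(0.3, size=(6, 8, 16)).astype(np.float64)
    behavior = rng.normal(size=(6, 2, 16))
    return spikes, behavior
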