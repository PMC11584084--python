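import numpy as np
import pytest

from eegrsa.config import SimulationConfig
from eegrsa.simulate import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study shared by read-mostly tests:
    16 entities, 16 channels, strong signal in 300-500 ms."""
    cfg = SimulationConfig(
        n_subjects=4,
        n_entities_per_cell=4,
        n_channels=16,
        vector_dim=8,
        snr=2.0,
        confound_beta=0.1,
        time_step_ms=20.0,
        seed=11,
    )
    montage, corpus, subjects = simulate_study(cfg)
    return cfg, montage, corpus, subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
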