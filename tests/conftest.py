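import numpy as np
import pytest

from cogvasc.io import make_task_design
from cogvasc.montage import default_montage
from cogvasc.simulate import SimConfig


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def design():
    return make_task_design(seed=0)


@pytest.fixture
def sim_config():
    """Small cohort at default study conditions."""
    return SimConfig(n_cn=3, n_mci=3, seed=11)


def noiseless_config(**kwargs) -> SimConfig:
    """Study config with every stochastic signal component switched off."""
    cfg = SimConfig(**{"n_cn": 1, "n_mci": 1, "seed": 5, **kwargs})
    cfg.noise = dict(cfg.noise, white_sd=0.0, cardiac_amp=0.0,
                     respiration_amp=0.0, mayer_amp=0.0, drift_amp=0.0)
    cfg.fc_signal_amp = 0.0
    cfg.amplitude_subject_sd = 0.0
    cfg.fc_coupling_subject_sd = 0.0
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
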