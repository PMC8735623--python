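import dataclasses

import numpy as np
import pytest

from macroquant import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile_config():
    """Noiseless default profile model (8 um line, dx 0.1, membrane at 4)."""
    return synthetic.ProfileSimConfig(seed=0, noise_sd=0.0)


@pytest.fixture
def calibrated_profile(profile_config):
    """One noiseless profile calibrated to a mem/cyto ratio of 1.15."""
    amp = synthetic.calibrate_profile_amplitude(1.15, profile_config)
    cfg = dataclasses.replace(profile_config, mem_amp=amp)
    return synthetic.simulate_profiles(cfg, 1)[0]
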