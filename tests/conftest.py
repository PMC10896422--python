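import numpy as np
import pytest

from dualtask_ef.preprocess import CleanerConfig
from dualtask_ef.synthetic import EEGSimConfig, GaitSimConfig


@pytest.fixture(scope="session")
def fast_eeg_cfg():
    """Low-rate EEG generator config for quick tests (still > 2x45 Hz)."""
    return EEGSimConfig(sampling_rate=128.0)


@pytest.fixture(scope="session")
def noise_free_gait_cfg():
    """Gait config with all noise sources off: metrics close exactly."""
    return GaitSimConfig(curve_noise_sd=0.0, stride_noise_sd=0.0,
                         subject_stride_sd=0.0)


@pytest.fixture(scope="session")
def cleaner_cfg():
    return CleanerConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
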