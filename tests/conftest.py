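import numpy as np
import pytest

from neuroassay import (
    MeaSimConfig,
    SignalRecording,
    bandpass_filter,
    generate_mea_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """Short 4-channel recording with basal spikes and one burst regime."""
    cfg = MeaSimConfig(
        n_channels=4, duration=5.0, basal_rate=4.0, burst_rate=12.0, seed=7
    )
    rec, gt = generate_mea_recording(cfg)
    return rec, gt, cfg


@pytest.fixture(scope="session")
def filtered_small_recording(small_recording):
    rec, gt, cfg = small_recording
    return bandpass_filter(rec), gt, cfg


def make_noise_recording(n_channels=2, duration=2.0, sigma=5.0, fs=20000.0, seed=0):
    r = np.random.default_rng(seed)
    sig = r.normal(0, sigma, (n_channels, int(duration * fs)))
    return SignalRecording(sig, fs)
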