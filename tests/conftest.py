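import numpy as np
import pytest

import taptone as tt


@pytest.fixture(scope="session")
def montage16():
    return tt.make_montage(16)


@pytest.fixture(scope="session")
def short_params():
    """A 5-minute, 8-channel session at 125 Hz — fast but fully featured."""
    return tt.SessionParams(duration_s=300.0, sfreq=125.0, n_channels=8, seed=17)


@pytest.fixture(scope="session")
def short_session(short_params):
    """(params, touches, tones, recording, ground truth) for the short session."""
    touches = tt.gen_touch_series(short_params)
    tones = tt.gen_tone_schedule(short_params)
    rec, gt = tt.gen_eeg(short_params, touches, tones)
    return short_params, touches, tones, rec, gt


@pytest.fixture(scope="session")
def clean_erp_session():
    """Noiseless session: evoked templates only (background/theta disabled)."""
    sp = tt.SessionParams(duration_s=300.0, sfreq=250.0, n_channels=8, seed=5,
                          noise_sd=0.0, offset0=-30.0, theta_log_power0=-30.0)
    touches = tt.gen_touch_series(sp)
    tones = tt.gen_tone_schedule(sp)
    rec, gt = tt.gen_eeg(sp, touches, tones)
    return sp, touches, tones, rec, gt


def rng(seed=0):
    return np.random.default_rng(seed)
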