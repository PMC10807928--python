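import numpy as np
import pytest

from voleabr import abr, synth
from voleabr.conditions import StimulusCondition


@pytest.fixture
def noiseless_female():
    """Female-mean session config with no epoch noise (template only)."""
    return synth.female_click_config(noise_sd_uv=0.0, n_epochs=1)


@pytest.fixture
def noiseless_male():
    return synth.male_click_config(noise_sd_uv=0.0, n_epochs=1)


@pytest.fixture
def click_left():
    return StimulusCondition("left", "click", 90.0)


def make_trace(values, fs=97656.25, **kwargs):
    return abr.AveragedTrace(values=np.asarray(values, dtype=float), fs=fs, **kwargs)


def gaussian_trace(fs, dur_ms, bumps):
    """Sum of Gaussian bumps [(amp, lat_ms, sigma_ms), ...] on a zero trace."""
    n = int(round(dur_ms * fs / 1000.0))
    t = np.arange(n) / fs * 1000.0
    y = np.zeros(n)
    for amp, lat, sig in bumps:
        y += amp * np.exp(-0.5 * ((t - lat) / sig) ** 2)
    return make_trace(y, fs=fs)
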