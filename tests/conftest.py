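import numpy as np
import pytest

from eegdynet.io import BandSpec, EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alpha_band():
    return BandSpec("Alpha", 8.0, 12.0)


def make_recording(data, fs=100.0, **kw):
    return EEGRecording(data=np.atleast_2d(data), fs=fs, **kw)


@pytest.fixture
def sine_pair():
    """A 10 Hz sinusoid and its quarter-cycle-delayed copy at 100 Hz."""
    fs = 100.0
    t = np.arange(0, 100, 1 / fs)
    x = np.sin(2 * np.pi * 10 * t)
    y = np.sin(2 * np.pi * 10 * t - np.pi / 2)
    return x, y, fs
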