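import numpy as np
import pytest

from pcgseg.audio_io import AudioSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_2k():
    """100 Hz Gaussian-windowed tone at 2 kHz, 1 s."""
    fs = 2000.0
    t = np.arange(int(fs)) / fs
    window = np.exp(-((t - 0.5) ** 2) / (2 * 0.05**2))
    return AudioSignal(np.sin(2 * np.pi * 100 * t) * window, fs)
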