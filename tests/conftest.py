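import numpy as np
import pytest

from pupiltag.preprocess import PupilTrace
from pupiltag.simulate import PupilModelParams


@pytest.fixture
def canonical_params():
    """Default (canonical-noise) simulator parameters."""
    return PupilModelParams()


@pytest.fixture
def quiet_params():
    """Noise-free, leakage-free simulator parameters for oracle checks."""
    return PupilModelParams(white_noise_sd=0.0, band_noise_amp=0.0, leakage=0.0)


def tone_trace(freq, duration=7.0, fs=333.0, amplitude=1.0, phase=0.0):
    """Pure sinusoid as a PupilTrace."""
    t = np.arange(int(round(duration * fs))) / fs
    return PupilTrace(amplitude * np.sin(2 * np.pi * freq * t + phase),
                      sampling_rate=fs)


@pytest.fixture
def make_tone():
    return tone_trace
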