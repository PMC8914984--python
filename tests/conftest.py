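import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from emgfatigue import EMGRecord, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq_hz, fs=2000.0, duration_s=3.0, amplitude=1.0, phase=0.0):
    """A pure cosine as an EMGRecord."""
    t = np.arange(round(duration_s * fs)) / fs
    return EMGRecord(amplitude * np.cos(2 * np.pi * freq_hz * t + phase), fs=fs)


def make_segment(samples, fs=2000.0, index=0, t_start=0.0):
    return Segment(samples=np.asarray(samples, dtype=float), index=index,
                   t_start=t_start, fs=fs)


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture
def seg():
    return make_segment


def rms(x):
    return float(np.sqrt(np.mean(np.square(np.asarray(x)))))


def edge_trimmed_rms(record, trim_s=0.25):
    k = round(trim_s * record.fs)
    return rms(record.samples[k:-k])
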