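import numpy as np
import pytest

from phasesom.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sine_recording(freqs, fs=500.0, duration=20.0, amplitudes=None, labels=None):
    """Recording whose channels are pure sinusoids at the given frequencies."""
    t = np.arange(int(duration * fs)) / fs
    freqs = np.atleast_1d(freqs)
    amplitudes = np.ones(len(freqs)) if amplitudes is None else np.atleast_1d(amplitudes)
    data = np.stack([a * np.cos(2 * np.pi * f * t) for f, a in zip(freqs, amplitudes)])
    labels = labels or [f"ch{i:02d}" for i in range(len(freqs))]
    return Recording(data=data, fs=fs, channel_labels=labels)


@pytest.fixture
def sine_recording():
    return make_sine_recording


@pytest.fixture
def noise_recording(rng):
    def make(n_channels=4, fs=500.0, duration=20.0):
        data = rng.standard_normal((n_channels, int(duration * fs)))
        return Recording(
            data=data, fs=fs,
            channel_labels=[f"ch{i:02d}" for i in range(n_channels)],
        )

    return make
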