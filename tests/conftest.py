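import numpy as np
import pandas as pd
import pytest

from insound.audio_io import AudioClip, DatasetManifest


def make_tone(freq_hz: float, sample_rate: float, n_samples: int, amplitude: float = 0.8) -> AudioClip:
    t = np.arange(n_samples) / sample_rate
    return AudioClip((amplitude * np.sin(2 * np.pi * freq_hz * t))[None, :], sample_rate)


@pytest.fixture
def tone_2500():
    """150 Hz tone in the reference preprocessed format: mono, 2500 Hz, 6250 samples."""
    return make_tone(150.0, 2500.0, 6250)


@pytest.fixture
def four_channel_clip():
    """A 4-channel 16 kHz 2500 ms clip, the reference recording format."""
    rng = np.random.default_rng(42)
    t = np.arange(40000) / 16000.0
    base = 0.5 * np.sin(2 * np.pi * 220.0 * t) + 0.05 * rng.normal(size=40000)
    samples = np.stack([g * base for g in (1.0, 0.9, 0.8, 0.7)])
    return AudioClip(samples, 16000.0)


@pytest.fixture
def balanced_manifest():
    """10 records in each of 12 classes."""
    rows = [
        {"path": f"clip_{c:02d}_{i:02d}.wav", "label": c, "split": "train"}
        for c in range(12)
        for i in range(10)
    ]
    return DatasetManifest(records=pd.DataFrame(rows), seed=0)
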