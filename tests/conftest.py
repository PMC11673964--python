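import numpy as np
import pytest

from ecgkit import EcgRecord, SynthConfig, generate_ecg


@pytest.fixture(scope="session")
def clean_record():
    """30 s clean synthetic ECG at 75 bpm, 360 Hz, with ground-truth marks."""
    return generate_ecg(SynthConfig(heart_rate=75.0, duration=30.0,
                                    sampling_rate=360.0, seed=0))


@pytest.fixture()
def zero_record():
    return EcgRecord(samples=np.zeros(3600), sampling_rate=360.0)


def sinusoid_record(freq_hz, fs=500.0, duration=10.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return EcgRecord(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                     sampling_rate=fs)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
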