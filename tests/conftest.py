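import numpy as np
import pytest

from ltmbeat import SynthConfig, synth_ecg


@pytest.fixture(scope="session")
def clean_record():
    """60 s, 2-lead clean synthetic ECG at 200 Hz with annotations."""
    cfg = SynthConfig(fs=200.0, duration_s=60.0, n_leads=2, mean_hr_bpm=60.0,
                      hr_jitter=0.05, seed=42)
    return synth_ecg(cfg)


@pytest.fixture(scope="session")
def clean_5min_record():
    """5 min, 2-lead clean synthetic ECG at 200 Hz."""
    cfg = SynthConfig(fs=200.0, duration_s=300.0, n_leads=2, mean_hr_bpm=60.0,
                      hr_jitter=0.05, seed=1)
    return synth_ecg(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
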