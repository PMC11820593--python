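import numpy as np
import pytest

from ecgfusion.synth import NoiseSpec, SynthConfig, add_noise, generate_clean_record


@pytest.fixture(scope="session")
def clean_ecg_4s():
    """A 4 s clean synthetic ECG at 96 bpm (fundamental above the
    1.5 Hz baseline cutoff) used across denoising tests."""
    return generate_clean_record(
        SynthConfig(360.0, 4.0, {"N": 1.0}, beat_rate_bpm=96.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_ecg_4s(clean_ecg_4s):
    return add_noise(
        clean_ecg_4s,
        NoiseSpec(baseline_amp=0.3, baseline_freq_hz=0.5, seed=2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
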