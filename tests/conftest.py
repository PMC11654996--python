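import numpy as np
import pytest

from cardiosync import (NOISE_PROFILES, render_ecg, render_ppg,
                        simulate_beat_times)


@pytest.fixture(scope="session")
def truth_60s():
    """Ground-truth beats: 70 bpm, mild HRV, 60 s."""
    return simulate_beat_times(70.0, 0.05, 60.0, seed=11)


@pytest.fixture(scope="session")
def clean_ppg_60s(truth_60s):
    return render_ppg(truth_60s, 134.0, 0.25, duration_s=60.0)


@pytest.fixture(scope="session")
def clean_ecg_60s(truth_60s):
    return render_ecg(truth_60s, 240.0, duration_s=60.0)


@pytest.fixture(scope="session")
def noisy_ecg_60s(truth_60s):
    noise = NOISE_PROFILES["moderate"].with_seed(5)
    return render_ecg(truth_60s, 240.0, noise, duration_s=60.0)
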