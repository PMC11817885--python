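import numpy as np
import pytest

import melpat as mp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """2-channel, 1 s, 500 Hz recording with known content."""
    gen = np.random.default_rng(0)
    return mp.EegRecording(
        data=gen.standard_normal((2, 500)) * 20.0,
        srate=500.0,
        channel_labels=["Fp1", "Cz"],
        subject_id="sub-001",
        condition_label="NS",
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two-class, 3-channel dataset small enough for fast model tests.

    2 subjects per class x 60 s -> 4 segments per recording, 16 segments
    per channel in total, with a large planted slow-band contrast.
    """
    recs = mp.generate_synthetic_dataset(
        n_subjects_per_class=2, n_channels=3, duration_seconds=60.0,
        srate=500.0, effect=mp.BandPowerEffect(theta_power_ratio=4.0),
        seed=7)
    return mp.build_dataset(recs)
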