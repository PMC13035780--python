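import numpy as np
import pytest

import qeeg


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-per-group synthetic cohort, shared across tests (read-only)."""
    return qeeg.synth_cohort(qeeg.CohortSpec(n_per_group=3, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Full feature table (bands + LZC + ApEn) for the small cohort."""
    return qeeg.compute_features(small_cohort.recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def clean_recording(rng):
    """A 24 s six-channel recording with realistic band structure."""
    chans = [
        20.0 * qeeg.synth_signal((0.45, 0.25, 0.19, 0.11), 0.5, 24.0, 1000.0,
                                 rng, osc_offset_hz=0.2 * (i - 2.5))
        for i in range(6)
    ]
    return qeeg.EEGRecording("s001", "T0", 1000.0, qeeg.REQUIRED_CHANNELS,
                             np.vstack(chans))
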