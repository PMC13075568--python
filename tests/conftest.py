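import numpy as np
import pytest

from capnet import envelope, synthetic


@pytest.fixture(scope="session")
def small_templates():
    return synthetic.make_templates(40, 6, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_templates):
    """4 participants, 40 ROIs, 60 s at 100 Hz; quick but structured."""
    return synthetic.simulate_roi_envelopes(
        small_templates,
        snr=1.0,
        n_participants=4,
        duration_s=60.0,
        fs=100.0,
        seed=8,
    )


@pytest.fixture(scope="session")
def small_frame_sets(small_cohort):
    return {
        p: envelope.zscore_rois(small_cohort.roi_env[p], small_cohort.fs).Z
        for p in range(small_cohort.n_participants)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
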