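import numpy as np
import pytest

from examvoice import features as ft
from examvoice import synthetic_cohort as sc


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight short recordings (~5-15 s) with audio, segmentations, timelines."""
    cfg = sc.SyntheticCohortConfig(
        n_recordings=8, duration_scale=0.02, tests_per_recording=2, seed=3
    )
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return [ft.extract_mfcc(r.waveform) for r in tiny_cohort.recordings]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
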