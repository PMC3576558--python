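import numpy as np
import pytest

import swallowscreen as sw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort40():
    """Seeded 40-participant cohort at full class separation (4 sd)."""
    return sw.simulate_cohort(sw.CohortConfig(n_participants=40, seed=1))


@pytest.fixture(scope="session")
def run40(cohort40):
    """End-to-end LOO evaluation of the 40-participant cohort."""
    return sw.evaluate_cohort(
        cohort40.recordings, cohort40.boundaries, cohort40.ratings, sw.RunConfig(seed=1)
    )


def make_clip(ap, si, fs, key=("P001", "teaspoon1", "b1", 1)):
    from swallowscreen.segmentation import SwallowClip

    return SwallowClip(*key, ap=np.asarray(ap, float), si=np.asarray(si, float),
                       fs=fs, start_s=0.0, end_s=len(ap) / fs)
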