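import numpy as np
import pytest

from neuroprog import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """32-subject synthetic cohort shared by structural tests."""
    cohort, truth = generate_cohort(SimConfig(n_subjects=32), seed=7)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
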