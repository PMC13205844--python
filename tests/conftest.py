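import numpy as np
import pytest

import softmark as sm


@pytest.fixture(scope="session")
def small_cohort():
    """Eight synthetic subjects, both views (16 images)."""
    return sm.generate_cohort(8, master_seed=42)


@pytest.fixture(scope="session")
def frontal_image(small_cohort):
    return next(im for im in small_cohort if im.view == "frontal")


@pytest.fixture(scope="session")
def profile_image(small_cohort):
    return next(im for im in small_cohort if im.view == "profile")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
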