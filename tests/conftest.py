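import numpy as np
import pytest

from olfbulb import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small phantom cohort shared by read-only tests (4 per group,
    reduced raster so generation stays fast)."""
    cfg = CohortConfig(n_pd=4, n_npod=4, n_control=4,
                       raster_shape=(260, 340), seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
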