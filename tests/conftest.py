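import numpy as np
import pytest

from datfuse import PhantomConfig, generate_cohort

#: Desk-scale grid used by most tests (geometry scales with the grid).
SMALL_GRID = (24, 30, 24)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-subject phantom cohort on a small grid, shared read-only."""
    return generate_cohort(
        PhantomConfig(n_hc=5, n_pd=5, grid_shape=SMALL_GRID, seed=11)
    )


@pytest.fixture(scope="session")
def atlas(small_cohort):
    return small_cohort.atlas


@pytest.fixture(scope="session")
def hc_volume(small_cohort):
    return small_cohort.volumes["HC001"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
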