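import numpy as np
import pytest

from cfcna import BinGrid, CohortConfig, SyntheticCohort


@pytest.fixture(scope="session")
def tiny_grid():
    """Two small chromosomes, 16 bins total, one masked bin."""
    grid = BinGrid.from_chromosomes([("1", 1_000_000), ("2", 600_000)],
                                    bin_width=100_000)
    mask = grid.mask.copy()
    mask[4] = False
    return grid.with_mask(mask)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-genome synthetic study shared by the slower tests."""
    return SyntheticCohort(CohortConfig(seed=7, scale=0.02, n_controls=40))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
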