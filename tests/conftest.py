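import numpy as np
import pytest

from braingap import synthdata as sd


@pytest.fixture(scope="session")
def small_atlas():
    """64-voxel atlas with 10-voxel signatures overlapping 50%."""
    return sd.make_phantom_atlas(grid_shape=(4, 4, 4), n_regions=2,
                                 signature_sizes=(10, 10),
                                 overlap_fraction=0.5, seed=7)


@pytest.fixture(scope="session")
def default_atlas():
    return sd.make_phantom_atlas(seed=1)


@pytest.fixture(scope="session")
def hc_cohort(small_atlas):
    """120 healthy controls on the small atlas."""
    cfg = sd.CohortConfig(group_sizes={"HC": 120}, n_sites=3)
    table, gmv, truth = sd.simulate_cohort(small_atlas, cfg, seed=11)
    return table, gmv, truth, cfg


@pytest.fixture(scope="session")
def mixed_cohort(small_atlas):
    """HC + patient groups with longitudinal follow-up."""
    cfg = sd.CohortConfig(group_sizes={"HC": 80, "SCZ": 40, "CHR": 30,
                                       "ROD": 30}, n_sites=3)
    table, gmv, truth = sd.simulate_cohort(small_atlas, cfg, seed=13)
    table = sd.simulate_longitudinal(table, truth, gamma=(0.5, 1.0), seed=14)
    return table, gmv, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
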