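import numpy as np
import pytest

from cvrquant import (
    GroundTruthParams,
    default_timeline,
    make_phantom_masks,
    simulate_subject,
)

SMALL_GRID = (24, 24, 12)
TINY_GRID = (16, 16, 8)
VOXEL_MM = 4.0


@pytest.fixture(scope="session")
def timeline():
    return default_timeline()


@pytest.fixture(scope="session")
def small_masks():
    return make_phantom_masks(SMALL_GRID, VOXEL_MM)


@pytest.fixture(scope="session")
def noiseless_params():
    return GroundTruthParams(
        cvr_true_gm=5.6,
        cvr_true_wm=5.1,
        noise_sd_asl=0.0,
        noise_sd_bold=0.0,
        drift_slope=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_params):
    """A confound-free synthetic session on a small grid."""
    return simulate_subject(
        noiseless_params, grid_dims=SMALL_GRID, voxel_size=VOXEL_MM
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
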