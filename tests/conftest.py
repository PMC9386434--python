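import numpy as np
import pytest

from infantfmri.paradigm import build_schedule, gamma_basis
from infantfmri.session import AcquisitionGeometry
from infantfmri.synthetic import EffectSpec, make_cohort, make_roi_masks


@pytest.fixture(scope="session")
def schedule():
    """Full 32-block, 960 s paradigm."""
    return build_schedule(seed=1)


@pytest.fixture(scope="session")
def small_geom():
    """Full-length session on a reduced grid for fast voxelwise work."""
    return AcquisitionGeometry(grid_shape=(12, 12, 12))


@pytest.fixture(scope="session")
def roi_small(small_geom):
    return make_roi_masks(small_geom.grid_shape)


@pytest.fixture(scope="session")
def noiseless_effects():
    return EffectSpec(sigma_thermal=0.0, drift_amplitude=0.0, beta_sd=0.0, hrf_peak_jitter_s=0.0)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_effects):
    return make_cohort(2, noiseless_effects, seed=0)[0]


@pytest.fixture(scope="session")
def hrf4():
    return gamma_basis(4.0)
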