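import numpy as np
import pytest

import petsubtype as pst
from petsubtype.simulate import CohortConfig, default_templates, generate_cross_sectional


@pytest.fixture(scope="session")
def atlas():
    return pst.generate_atlas()


@pytest.fixture(scope="session")
def templates(atlas):
    return default_templates(atlas)


@pytest.fixture(scope="session")
def default_cohort(atlas, templates):
    """One full-size cohort at the default study conditions (seed 0)."""
    return generate_cross_sectional(atlas, templates, CohortConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic limit: no noise sources, severity fixed at the group mean."""
    return CohortConfig(n_cn=6, n_ad=12, n_mci=8, voxel_noise_sd=0.0,
                        global_factor_sd=0.0, ref_region_sd=0.0,
                        severity_fixed=True, seed=3)


@pytest.fixture(scope="session")
def noiseless_cohort(atlas, templates, noiseless_config):
    return generate_cross_sectional(atlas, templates, noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
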