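import numpy as np
import pytest

from petasym import CohortConfig, generate_atlas, generate_feature_table


@pytest.fixture(scope="session")
def atlas():
    """Small mirror-symmetric atlas shared across tests."""
    return generate_atlas((32, 32, 24), voxel_size=(2.0, 2.0, 2.0), seed=1)


@pytest.fixture
def noise_free_config():
    return CohortConfig(voxel_noise_sd=0.0, ai_noise_sd=0.0,
                        global_scale_range=(1.0, 1.0), seed=7)


@pytest.fixture
def cohort_table():
    """Default study-condition feature table (n=49, 27:22, planted effects)."""
    return generate_feature_table(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
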