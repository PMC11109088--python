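import numpy as np
import pytest

from qmripd.core import AIF
from qmripd.phantom import CohortConfig, TreatmentEffectModel, generate_ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_patients=1, shape=(24, 24, 6),
                        tumor_radius_vox=(3.0, 4.0))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_ground_truth(small_config, TreatmentEffectModel.null(), seed=7)


@pytest.fixture(scope="session")
def small_scene(small_cohort):
    return small_cohort.scenes["P001"]["baseline"]


@pytest.fixture
def step_aif():
    """Unit-step plasma concentration from t = 0 on an 8 s grid."""
    t = np.arange(0, 400.0, 8.0)
    return AIF(times_s=t, cp_mM=np.ones_like(t))
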