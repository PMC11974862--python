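import numpy as np
import pytest
from hypothesis import settings

from elastoage.evaluation import build_phantom_dataset
from elastoage.synthetic import CohortSpec, build_atlas

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas24():
    return build_atlas((24, 24, 24), 2.0, seed=0)


@pytest.fixture(scope="session")
def atlas32():
    return build_atlas((32, 40, 32), 2.0, seed=0)


@pytest.fixture(scope="session")
def healthy_ds(atlas24):
    """Desk-scale healthy cohort with the default aging trends and mild noise."""
    spec = CohortSpec(n_healthy=60, noise_sd=0.02, seed=0)
    return build_phantom_dataset(spec, atlas24)


@pytest.fixture(scope="session")
def disease_ds(atlas24):
    """Cohort with MCI/AD subjects and flagged matched controls."""
    spec = CohortSpec(n_healthy=40, n_mci=10, n_ad=10, n_control_mci=8,
                      n_control_ad=8, noise_sd=0.02, seed=3)
    return build_phantom_dataset(spec, atlas24)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
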