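import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gauss1d():
    from statemap.observation_models import GaussianModel

    return GaussianModel.default(1)


@pytest.fixture(scope="session")
def vm_model():
    from statemap.observation_models import VonMisesModel

    return VonMisesModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
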