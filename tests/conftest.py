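import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memti.materials import default_geometry, load_default_aln, load_default_metglas

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def metglas():
    return load_default_metglas()


@pytest.fixture(scope="session")
def aln():
    return load_default_aln()


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
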