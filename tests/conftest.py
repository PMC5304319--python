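import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from minmaxfit import FitnessVector

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fv13():
    return FitnessVector.from_values([1.0, 3.0])


def random_fitness(seed: int, n: int = 12, sigma: float = 1.0) -> FitnessVector:
    gen = np.random.default_rng(seed)
    return FitnessVector.from_values(gen.lognormal(0.0, sigma, n))


def random_simplex(seed: int, n: int) -> np.ndarray:
    gen = np.random.default_rng(seed)
    return gen.dirichlet(np.ones(n))
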