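import numpy as np
import pytest

from obesinet.population import Person
from obesinet.synthetic import SyntheticSpec, generate_population


def make_person(id=0, age=40, sex="male", height_m=1.70, bw0=70.0, bw1=None, ei=2400.0):
    return Person(id=id, age=age, sex=sex, height_m=height_m,
                  bw0=bw0, bw1=bw0 if bw1 is None else bw1, ei=ei)


@pytest.fixture(scope="session")
def small_population():
    """120 synthetic persons, enough for network/dynamics integration tests."""
    return generate_population(SyntheticSpec(n=120, seed=11))


@pytest.fixture(scope="session")
def medium_population():
    """500 synthetic persons for the replicate-level experiments."""
    return generate_population(SyntheticSpec(n=500, seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
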