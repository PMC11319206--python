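import numpy as np
import pytest

from mtmosaic import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_genome():
    return sd.generate_toy_genome(seed=1, length=2000)


@pytest.fixture(scope="session")
def small_cohort(toy_genome):
    """A compact generated cohort shared by IO / noise / classification
    tests: (cohort, truth, calls)."""
    return sd.generate_cohort(sd.example_config(seed=3), toy_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
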