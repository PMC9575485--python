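import numpy as np
import pytest

from pippk import PopulationParameters, generate_population


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    """Final-model population parameters (the package defaults)."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def virtual_children_10k():
    """The 10,000-child virtual population used for full-scale checks."""
    return generate_population(10000, seed=20210)


@pytest.fixture(scope="session")
def virtual_children_2k():
    """A smaller population for cheaper Monte-Carlo property checks."""
    return generate_population(2000, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
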