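import numpy as np
import pytest

from reachdepth import geometry3d as g3d
from reachdepth.fixtures import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def tiny_set(fixtures):
    return fixtures.tiny_set


@pytest.fixture(scope="session")
def small_set():
    """A few hundred generated scenes shared across suites."""
    return g3d.generate_training_set(300, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
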