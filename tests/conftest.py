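import numpy as np
import pytest

from cyclopept.fixtures import make_c2_ring
from cyclopept.sampling import generate_library


@pytest.fixture(scope="session")
def small_library():
    """A small deterministic loop library shared across tests."""
    return generate_library({3: 12, 4: 8, 5: 6}, seed=11)


@pytest.fixture(scope="session")
def mc1_ring():
    """C2-symmetric 8-ring carrying the MC1 sequence (two transannular
    hydrogen bonds, two cis amides)."""
    return make_c2_ring(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
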