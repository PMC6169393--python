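import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture
def random_seq():
    """Factory for random ACGT strings from an explicit generator."""

    def make(rng, n, alphabet="ACGT"):
        return "".join(rng.choice(list(alphabet), size=n))

    return make
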