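import numpy as np
import pytest

from minivote.params import Params
from minivote.seqio import ReferenceSequence

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def small_params():
    """Full-size hashing parameters on a desk-scale window."""
    return Params(W=100, k_mh=10, v=10, seed=11)


@pytest.fixture
def tiny_refs(rng):
    return [ReferenceSequence("c1", random_dna(rng, 1000), 0)]
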