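import numpy as np
import pytest

from linearmito.genome_io import GeneFeature, LinearMitogenome
from linearmito.synthetic import SimParams, generate_mitogenome


@pytest.fixture
def rng():
    return np.random.default_rng(20211)


@pytest.fixture(scope="session")
def small_params():
    """A compact but architecturally complete genome for fast tests."""
    return SimParams(seed=11, genome_len=22_000, n_genes=18, overlap_events=4)


@pytest.fixture(scope="session")
def small_genome(small_params):
    return generate_mitogenome(small_params)


def random_dna(rng, n, at_bias=0.5):
    p = [at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2, at_bias / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
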