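import numpy as np
import pytest

from cisenrich import default_registry, generate_pool
from cisenrich.scanner import count_occurrences


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def genomic_pool():
    """Genome-scale null pool: 30000 promoters of 1000 bp at balanced GC,
    shared by the calibration and background-moment checks."""
    return generate_pool(30000, 1000, 0.5, rng=np.random.default_rng(20111))


@pytest.fixture(scope="session")
def genomic_counts(genomic_pool, registry):
    """Per-promoter counts of the moderately frequent MRE1 (pool presence
    ~0.6, near-Gaussian presence background) and the overabundant MRE2
    (presence ~0.9996, the non-Gaussian parameter-I case)."""
    return count_occurrences(genomic_pool, ["MRE1", "MRE2"], registry)
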