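import numpy as np
import pytest

from tagback import QCThresholds, parse_motif
from tagback.synth import SyntheticSpec, generate_synthetic_genome


@pytest.fixture(scope="session")
def cas9():
    return parse_motif("N{17}|N{3}>NGG")


@pytest.fixture(scope="session")
def plain_cas9():
    return parse_motif("N{20}>NGG")


@pytest.fixture
def thresholds():
    return QCThresholds()


@pytest.fixture(scope="session")
def small_genome():
    """5 kb single-haplotype genome, fixed seed."""
    return generate_synthetic_genome(SyntheticSpec(length=5000, seed=42)).genome


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
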