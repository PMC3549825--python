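import numpy as np
import pytest

from subphylo.seqio import GenomeSequence, build_extended


def genome(label: str, residues: str) -> GenomeSequence:
    return GenomeSequence(label=label, residues=residues)


@pytest.fixture
def table_pair():
    """The worked-example pair used throughout the matching-statistics tests."""
    return genome("s1", "ACACGTAC"), genome("s2", "TACGTGTA")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_genome(rng, label: str, length: int) -> GenomeSequence:
    residues = "".join(rng.choice(list("ACGT"), size=length))
    return genome(label, residues)


def random_pair(rng, min_len: int = 10, max_len: int = 100):
    n1 = int(rng.integers(min_len, max_len + 1))
    n2 = int(rng.integers(min_len, max_len + 1))
    return random_genome(rng, "a", n1), random_genome(rng, "b", n2)


def extended_of(seq: GenomeSequence):
    return build_extended(seq)
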