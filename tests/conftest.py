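import random

import pytest

from gapminer.index import build_index
from gapminer.seqdb import Alphabet, Sequence, SequenceDatabase

WORKED_SEQS = [("X", "ATACGAT"), ("Y", "ATCACGA"), ("Z", "TAACGCA")]


@pytest.fixture
def worked_db() -> SequenceDatabase:
    """Three-sequence DNA database used throughout: X=ATACGAT, Y=ATCACGA, Z=TAACGCA."""
    return SequenceDatabase(Alphabet.dna(), [Sequence(i, s) for i, s in WORKED_SEQS])


@pytest.fixture
def worked_index(worked_db):
    return build_index(worked_db)


def random_db(rng: random.Random, A: int = 4, max_len: int = 12, max_n: int = 10) -> SequenceDatabase:
    """Small random database for oracle-equivalence checks."""
    alphabet = Alphabet.custom(list("ACGTFHKL"[:A])) if A != 4 else Alphabet.dna()
    n = rng.randint(1, max_n)
    seqs = [
        Sequence(f"R{j:03d}", "".join(rng.choice(alphabet.items) for _ in range(rng.randint(0, max_len))))
        for j in range(n)
    ]
    return SequenceDatabase(alphabet, seqs)
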