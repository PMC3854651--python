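"""Seeded synthetic sequence generation.

Sequences are i.i.d. uniform draws over the first ``A`` letters of the
matching alphabet (DNA when ``A=4``, protein when ``A=20``, otherwise the
leading letters of A..Z).  Each sequence has its own deterministic stream
derived from the master seed, so growing ``N`` never reshuffles earlier
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase

import numpy as np

from gapminer.seqdb import Alphabet, Sequence, SequenceDatabase


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters: alphabet size, sequence length, sequence count,
    master seed.  Identical specs yield byte-identical databases."""

    A: int
    L: int
    N: int
    seed: int

    def __post_init__(self) -> None:
        if not 1 <= self.A <= 26:
            raise ValueError(f"alphabet size must be in 1..26, got {self.A}")
        if self.L < 0:
            raise ValueError(f"sequence length must be >= 0, got {self.L}")
        if self.N < 0:
            raise ValueError(f"sequence count must be >= 0, got {self.N}")

    def alphabet(self) -> Alphabet:
        if self.A == 4:
            return Alphabet.dna()
        if self.A == 20:
            return Alphabet.protein()
        return Alphabet.custom(ascii_uppercase[: self.A])

    def describe(self) -> str:
        return f"A={self.A} L={self.L} N={self.N} seed={self.seed}"


def generate_db(spec: SynthSpec) -> SequenceDatabase:
    """Generate ``N`` sequences of exact length ``L``, ids ``S000001``... in
    order, residues uniform i.i.d. over the alphabet."""
    alphabet = spec.alphabet()
    letters = np.array(list(alphabet.items))
    sequences = []
    for j in range(1, spec.N + 1):
        rng = np.random.default_rng([spec.seed, j])
        draw = rng.integers(0, spec.A, size=spec.L)
        sequences.append(Sequence(f"S{j:06d}", "".join(letters[draw])))
    return SequenceDatabase(alphabet, sequences)
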