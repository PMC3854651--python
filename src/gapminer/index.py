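"""Inverted position index over (item, sequence, position) triples.

The index is built in a single pass over the database and stores, for every
(item, sequence-number) pair, the strictly increasing list of 1-based
positions at which the item occurs.  Windowed successor queries are answered
by binary search.
"""

from __future__ import annotations

import io
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from gapminer.seqdb import Alphabet, SequenceDatabase


@dataclass
class PositionIndex:
    """Per-(item, sequence) sorted occurrence-position lists.

    ``table[item][j-1]`` is the sorted position list of ``item`` in sequence
    number ``j`` (1-based sequence numbering follows database order).
    """

    alphabet: Alphabet
    N: int
    table: dict[str, list[list[int]]]
    sequence_ids: list[str]

    def _check(self, item: str, seq: int) -> None:
        if item not in self.table:
            raise KeyError(f"item {item!r} not in alphabet {self.alphabet.name!r}")
        if not 1 <= seq <= self.N:
            raise IndexError(f"sequence number {seq} out of range 1..{self.N}")


def build_index(db: SequenceDatabase) -> PositionIndex:
    """Build the position index by scanning ``db`` once.

    Every residue is indexed exactly once, so the total number of indexed
    positions equals the sum of sequence lengths.
    """
    table: dict[str, list[list[int]]] = {item: [[] for _ in range(db.N)] for item in db.alphabet}
    for j, seq in enumerate(db):
        for pos, residue in enumerate(seq.residues, start=1):
            table[residue][j].append(pos)
    return PositionIndex(alphabet=db.alphabet, N=db.N, table=table, sequence_ids=db.ids())


def positions_of(index: PositionIndex, item: str, seq: int) -> list[int]:
    """The stored strictly increasing position list of ``item`` in sequence
    number ``seq`` (1-based).  Read-only: callers must not mutate the result.
    """
    index._check(item, seq)
    return index.table[item][seq - 1]


def successors_in_window(index: PositionIndex, item: str, seq: int, p: int, G: int) -> list[int]:
    """All positions ``q`` of ``item`` in sequence ``seq`` with ``p < q < p + G``.

    The window is a strict double inequality, so ``G=1`` never admits a
    successor and ``G=2`` admits only the adjacent position ``p + 1``.
    """
    if G < 1:
        raise ValueError(f"gap constraint must be >= 1, got {G}")
    if p < 1:
        raise ValueError(f"position must be >= 1, got {p}")
    row = positions_of(index, item, seq)
    lo = bisect_right(row, p)
    hi = bisect_left(row, p + G)
    return row[lo:hi]


def dump_index_tsv(index: PositionIndex, path: Union[str, Path, io.TextIOBase]) -> None:
    """Debug dump as TSV rows (item, sequence_id, position)."""

    def _write(handle: io.TextIOBase) -> None:
        handle.write("item\tsequence_id\tposition\n")
        for item in index.alphabet:
            for j in range(1, index.N + 1):
                for pos in index.table[item][j - 1]:
                    handle.write(f"{item}\t{index.sequence_ids[j - 1]}\t{pos}\n")

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8") as handle:
            _write(handle)
    else:
        _write(path)
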