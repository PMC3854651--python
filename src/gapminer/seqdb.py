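"""Alphabets, the sequence-database model, and FASTA / line-oriented I/O.

Positions are 1-based everywhere in this package: residue ``i`` of a sequence
occupies position ``i`` with ``1 <= i <= n``.  Sequences are unaligned; the
gap character ``-`` is rejected on input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_LETTERS = ("A", "C", "G", "T")
PROTEIN_LETTERS = tuple("ACDEFGHIKLMNPQRSTVWY")

_FORMATS = ("fasta", "lines")
_UNKNOWN_POLICIES = ("error", "drop-sequence", "keep-as-item")


class SequenceDatabaseError(ValueError):
    """Raised for malformed input files or symbol-policy violations."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered, reproducible set of single-character symbols.

    The iteration order of :attr:`items` is fixed; the depth-first miner
    spells candidate extensions in exactly this order, which makes mining
    output deterministic.
    """

    name: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("alphabet must contain at least one symbol")
        seen = set()
        for sym in self.items:
            if len(sym) != 1 or sym != sym.upper() or sym.isspace():
                raise ValueError(f"invalid alphabet symbol: {sym!r}")
            if sym in seen:
                raise ValueError(f"duplicate alphabet symbol: {sym!r}")
            seen.add(sym)

    @property
    def size(self) -> int:
        return len(self.items)

    def __contains__(self, sym: object) -> bool:
        return sym in self.items

    def __iter__(self) -> Iterator[str]:
        return iter(self.items)

    def extended(self, extra: Iterable[str]) -> "Alphabet":
        """Return a custom alphabet with ``extra`` symbols appended in order."""
        new_items = list(self.items)
        for sym in extra:
            if sym not in new_items:
                new_items.append(sym)
        if tuple(new_items) == self.items:
            return self
        return Alphabet("custom", tuple(new_items))

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls("dna", DNA_LETTERS)

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls("protein", PROTEIN_LETTERS)

    @classmethod
    def custom(cls, items: Iterable[str]) -> "Alphabet":
        return cls("custom", tuple(items))


@dataclass(frozen=True)
class Sequence:
    """A named, 1-based-indexed string of residues."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def at(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} out of range for sequence {self.id!r}")
        return self.residues[position - 1]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceDatabase:
    """An ordered collection of sequences over a declared alphabet.

    Sequence order is stable and significant: row ``j`` of every counting
    matrix and every index refers to ``sequences[j-1]``.
    """

    alphabet: Alphabet
    sequences: list[Sequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceDatabaseError(f"duplicate sequence ids: {dupes}")

    @property
    def N(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __getitem__(self, idx: int) -> Sequence:
        return self.sequences[idx]

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


def _detect_alphabet(residue_sets: set[str]) -> Alphabet:
    # auto policy: DNA when every residue is in {A,C,G,T,N}, otherwise protein
    if residue_sets <= set("ACGTN"):
        return Alphabet.dna()
    return Alphabet.protein()


def _resolve_alphabet(policy: Union[str, TypingSequence[str]], residues_seen: set[str]) -> Alphabet:
    if isinstance(policy, str):
        if policy == "dna":
            return Alphabet.dna()
        if policy == "protein":
            return Alphabet.protein()
        if policy == "auto":
            return _detect_alphabet(residues_seen)
        raise ValueError(f"unknown alphabet policy: {policy!r}")
    return Alphabet.custom(policy)


def _read_fasta(handle: io.TextIOBase) -> list[tuple[str, str]]:
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        records.append((rec.id, str(rec.seq)))
    return records


def _read_lines(handle: io.TextIOBase) -> list[tuple[str, str]]:
    records = []
    for i, raw in enumerate(handle, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if "\t" in line:
            seq_id, residues = line.split("\t", 1)
        else:
            seq_id, residues = f"L{i:06d}", line
        records.append((seq_id, residues.strip()))
    return records


def load_sequences(
    path: Union[str, Path, io.TextIOBase],
    format: str = "fasta",
    alphabet_policy: Union[str, TypingSequence[str]] = "auto",
    unknown_policy: str = "keep-as-item",
) -> SequenceDatabase:
    """Read a sequence database from ``path``.

    Parameters
    ----------
    path:
        File path or open text handle.
    format:
        ``"fasta"`` (multi-line bodies allowed) or ``"lines"`` (one sequence
        per line, optional leading ``id<TAB>``).
    alphabet_policy:
        ``"dna"``, ``"protein"``, ``"auto"`` (DNA iff all residues are in
        ``{A,C,G,T,N}``), or an explicit list of symbols.
    unknown_policy:
        What to do with residues outside the resolved alphabet:
        ``"error"`` raises naming the sequence id and position,
        ``"drop-sequence"`` discards the offending sequence,
        ``"keep-as-item"`` (default) appends the symbol to a custom alphabet.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if unknown_policy not in _UNKNOWN_POLICIES:
        raise ValueError(f"unknown_policy must be one of {_UNKNOWN_POLICIES}, got {unknown_policy!r}")

    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8", newline=None) as handle:
            raw = _read_fasta(handle) if format == "fasta" else _read_lines(handle)
    else:
        raw = _read_fasta(path) if format == "fasta" else _read_lines(path)

    if not raw:
        raise SequenceDatabaseError("empty database: no sequences found")

    raw = [(sid, res.upper()) for sid, res in raw]
    for sid, res in raw:
        if "-" in res:
            raise SequenceDatabaseError(f"gap character '-' in sequence {sid!r}: sequences must be unaligned")

    residues_seen = set("".join(res for _, res in raw))
    alphabet = _resolve_alphabet(alphabet_policy, residues_seen)

    kept: list[Sequence] = []
    extras: list[str] = []
    for sid, res in raw:
        bad = next(((i, c) for i, c in enumerate(res, start=1) if c not in alphabet and c not in extras), None)
        if bad is None:
            kept.append(Sequence(sid, res))
            continue
        if unknown_policy == "error":
            pos, sym = bad
            raise SequenceDatabaseError(
                f"unknown symbol {sym!r} at position {pos} of sequence {sid!r} "
                f"(alphabet {alphabet.name!r})"
            )
        if unknown_policy == "drop-sequence":
            continue
        for c in res:  # keep-as-item
            if c not in alphabet and c not in extras:
                extras.append(c)
        kept.append(Sequence(sid, res))

    if extras:
        alphabet = alphabet.extended(extras)
    if not kept:
        raise SequenceDatabaseError("empty database: all sequences dropped by unknown_policy")
    return SequenceDatabase(alphabet, kept)


def write_sequences(
    db: SequenceDatabase,
    path: Union[str, Path, io.TextIOBase],
    format: str = "fasta",
    header_comment: str | None = None,
) -> None:
    """Write ``db`` so that :func:`load_sequences` round-trips ids, residues
    and order exactly.  ``header_comment`` is placed in each FASTA description.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if db.N == 0:
        raise SequenceDatabaseError("refusing to write an empty database")

    def _write(handle: io.TextIOBase) -> None:
        if format == "fasta":
            records = [
                SeqRecord(Seq(s.residues), id=s.id, description=header_comment or "")
                for s in db
            ]
            SeqIO.write(records, handle, "fasta")
        else:
            for s in db:
                handle.write(f"{s.id}\t{s.residues}\n")

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            _write(handle)
    else:
        _write(path)
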