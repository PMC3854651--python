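"""Reference miners: a brute-force enumerator and a projected-database miner.

Both produce the same (pattern, support) sets as the depth-first index miner
and exist as correctness oracles and runtime comparators.  Gap semantics are
identical across all three miners: consecutive matched positions ``p, q``
must satisfy the strict window ``p < q < p + G``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Union

from gapminer.miner import GappedPattern, MiningParams, resolve_threshold
from gapminer.seqdb import Sequence, SequenceDatabase

BRUTE_FORCE_GUARD = 10**6


def contains_gapped(seq: Sequence, pattern: GappedPattern) -> bool:
    """True iff ``seq`` contains an occurrence of ``pattern``.

    An occurrence is a position chain ``q_1 < q_2 < ... < q_m`` with
    ``residue(q_i) = items[i]`` and ``q_{i+1} < q_i + G`` for every adjacent
    pair.  Implemented as a left-to-right scan that keeps ALL live end
    positions of the prefix matched so far — a greedy minimum-position scan
    would be incomplete.
    """
    G = pattern.gap
    residues = seq.residues
    live = [i + 1 for i, c in enumerate(residues) if c == pattern.items[0]]
    for item in pattern.items[1:]:
        if not live:
            return False
        nxt: set[int] = set()
        for p in live:
            for q in range(p + 1, min(p + G, len(residues) + 1)):
                if residues[q - 1] == item:
                    nxt.add(q)
        live = sorted(nxt)
    return bool(live)


def brute_force_mine(
    db: SequenceDatabase,
    params: MiningParams,
    max_len: int,
) -> set[tuple[str, int]]:
    """Enumerate every item sequence of length 1..``max_len``, count support
    by direct containment, and return the (pattern string, support) pairs
    meeting the threshold.  Guarded to ``A**max_len <= 10**6`` candidates."""
    A = db.alphabet.size
    if A**max_len > BRUTE_FORCE_GUARD:
        raise ValueError(f"brute-force guard exceeded: {A}**{max_len} > {BRUTE_FORCE_GUARD}")
    threshold = resolve_threshold(params, db.N)
    out: set[tuple[str, int]] = set()
    for length in range(1, max_len + 1):
        for combo in itertools.product(db.alphabet.items, repeat=length):
            pattern = GappedPattern(combo, params.gap)
            support = sum(1 for seq in db if contains_gapped(seq, pattern))
            if support >= threshold:
                out.add((str(pattern), support))
    return out


@dataclass
class ProjectedDatabase:
    """Pseudo-projection of a database on a pattern's last item.

    ``entries`` holds one ``(sequence number, last-item position)`` pair per
    occurrence of the prefix's last item; the suffix it represents starts at
    the position immediately after.  Occurrences at the end of a sequence
    (empty suffix) are omitted.  Entries preserve database order.
    """

    prefix: GappedPattern
    entries: list[tuple[int, int]]

    def suffixes(self, db: SequenceDatabase) -> list[str]:
        """Materialize the represented suffix strings (fixture/debug use)."""
        return [db.sequences[j - 1].residues[p:] for j, p in self.entries]


def project(
    source: Union[SequenceDatabase, ProjectedDatabase],
    item: str,
    gap: int,
    db: SequenceDatabase | None = None,
) -> ProjectedDatabase:
    """Project on ``item``: one entry per qualifying occurrence of ``item``,
    each representing the suffix strictly after that occurrence.

    From a database, every occurrence of ``item`` qualifies.  From an
    existing projection, an occurrence qualifies when it falls inside the
    strict gap window of the entry that spawned it (``db`` must then be the
    projection's underlying database).  Empty suffixes are dropped.
    """
    entries: list[tuple[int, int]] = []
    if isinstance(source, SequenceDatabase):
        prefix = GappedPattern((item,), gap)
        for j, seq in enumerate(source, start=1):
            for pos, residue in enumerate(seq.residues, start=1):
                if residue == item and pos < seq.length:
                    entries.append((j, pos))
        return ProjectedDatabase(prefix, entries)

    if db is None:
        raise ValueError("projecting a projection requires the underlying database")
    prefix = source.prefix.extended(item)
    seen: set[tuple[int, int]] = set()
    for j, p in source.entries:
        residues = db.sequences[j - 1].residues
        for q in range(p + 1, min(p + gap, len(residues) + 1)):
            if residues[q - 1] == item and q < len(residues) and (j, q) not in seen:
                seen.add((j, q))
                entries.append((j, q))
    entries.sort()
    return ProjectedDatabase(prefix, entries)


def frequent_items_in_projection(
    db: SequenceDatabase,
    proj: ProjectedDatabase,
    gap: int,
) -> dict[str, int]:
    """Support of each alphabet item one windowed step beyond ``proj``.

    For every entry ``(j, p)`` the suffix positions ``p < q < p + gap`` are
    scanned; each sequence contributes at most one count per item.
    """
    per_item_seqs: dict[str, set[int]] = {item: set() for item in db.alphabet}
    for j, p in proj.entries:
        residues = db.sequences[j - 1].residues
        for q in range(p + 1, min(p + gap, len(residues) + 1)):
            per_item_seqs[residues[q - 1]].add(j)
    return {item: len(seqs) for item, seqs in per_item_seqs.items() if seqs}


def genprefixspan_mine(
    db: SequenceDatabase,
    params: MiningParams,
) -> set[tuple[str, int]]:
    """Projected-database pattern-growth miner.

    Scans the database for frequent single items, builds a pseudo-projection
    per frequent item, then recursively scans each projection for items
    frequent within the gap window of each entry, projecting again until no
    frequent extension exists.  Returns the same (pattern, support) set as
    the index-based miner.
    """
    threshold = resolve_threshold(params, db.N)
    if threshold > db.N:
        return set()
    G = params.gap
    max_length = params.max_length or float("inf")
    out: set[tuple[str, int]] = set()

    def recurse(proj: ProjectedDatabase) -> None:
        if proj.prefix.length >= max_length:
            return
        counts = frequent_items_in_projection(db, proj, G)
        for item in db.alphabet:
            support = counts.get(item, 0)
            if support < threshold:
                continue
            pattern = proj.prefix.extended(item)
            if pattern.length >= params.min_length:
                out.add((str(pattern), support))
            recurse(project(proj, item, G, db=db))

    for item in db.alphabet:
        containing = [j for j, seq in enumerate(db, start=1) if item in seq.residues]
        support = len(containing)
        if support < threshold:
            continue
        if params.min_length <= 1:
            out.add((item, support))
        recurse(project(db, item, G))
    return out
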