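"""Depth-first spelling of gapped sequential patterns.

A candidate pattern's sole per-pattern state is its counting matrix: for
every sequence, the set of positions at which an occurrence of the pattern
can end.  Appending an item turns each end position ``p`` into the window
``p < q < p + G`` of the new item's occurrences; support is the number of
sequences whose row is non-empty.  Support never grows under extension, so
any candidate below the threshold prunes its whole subtree.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

from gapminer.index import PositionIndex, build_index, positions_of, successors_in_window
from gapminer.seqdb import SequenceDatabase

logger = logging.getLogger(__name__)

PATTERN_SEPARATOR = "*"


@dataclass(frozen=True)
class GappedPattern:
    """An ordered list of items with one global gap constraint ``G``.

    The canonical string form joins items with ``"*"`` (e.g. ``"C*A"``);
    ``G`` is metadata and is not encoded in the string.
    """

    items: tuple[str, ...]
    gap: int

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("pattern must contain at least one item")
        if self.gap < 1:
            raise ValueError(f"gap constraint must be >= 1, got {self.gap}")

    @property
    def length(self) -> int:
        return len(self.items)

    def extended(self, item: str) -> "GappedPattern":
        return GappedPattern(self.items + (item,), self.gap)

    def __str__(self) -> str:
        return PATTERN_SEPARATOR.join(self.items)


@dataclass
class CountingMatrix:
    """One row per sequence number; each row is the strictly increasing,
    duplicate-free list of positions where the current pattern can end.
    Empty rows are legal (rendered as ``(-)``)."""

    rows: list[list[int]]

    @property
    def N(self) -> int:
        return len(self.rows)

    def __str__(self) -> str:
        parts = []
        for row in self.rows:
            parts.append("(" + ",".join(map(str, row)) + ")" if row else "(-)")
        return "{" + ",".join(parts) + "}"


@dataclass
class MiningParams:
    """Mining parameters.

    Exactly one of ``min_support`` (absolute count) and ``min_support_frac``
    (fraction of N, resolved by ceiling) must be given.
    """

    gap: int
    min_support: Optional[int] = None
    min_support_frac: Optional[float] = None
    min_length: int = 1
    max_length: Optional[int] = None
    report_positions: bool = False

    def __post_init__(self) -> None:
        if self.gap < 1:
            raise ValueError(f"gap constraint must be >= 1, got {self.gap}")
        if (self.min_support is None) == (self.min_support_frac is None):
            raise ValueError("exactly one of min_support and min_support_frac is required")
        if self.min_support is not None and self.min_support < 1:
            raise ValueError(f"min_support must be >= 1, got {self.min_support}")
        if self.min_support_frac is not None and not 0.0 < self.min_support_frac <= 1.0:
            raise ValueError(f"min_support_frac must lie in (0, 1], got {self.min_support_frac}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < 1:
            raise ValueError("max_length must be >= 1")


@dataclass
class MotifRecord:
    """A pattern that met the minimum support."""

    pattern: GappedPattern
    support: int
    supporting_ids: Optional[list[str]] = None
    end_positions: Optional[CountingMatrix] = None


def resolve_threshold(params: MiningParams, N: int) -> int:
    """The absolute support threshold: ``min_support`` if given, else
    ``ceil(min_support_frac * N)``.  Always >= 1.  A threshold above ``N``
    is legal but unreachable; a warning is logged."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if params.min_support is not None:
        threshold = params.min_support
    else:
        threshold = math.ceil(params.min_support_frac * N)
    threshold = max(threshold, 1)
    if threshold > N:
        logger.warning("support threshold %d exceeds N=%d: no pattern can qualify", threshold, N)
    return threshold


def initial_matrix(index: PositionIndex, item: str) -> CountingMatrix:
    """Counting matrix of the single-item pattern ``item``: row ``j`` is the
    full occurrence-position list of the item in sequence ``j``."""
    return CountingMatrix([list(positions_of(index, item, j)) for j in range(1, index.N + 1)])


def extend_matrix(index: PositionIndex, parent: CountingMatrix, item: str, G: int) -> CountingMatrix:
    """Extend a pattern's counting matrix by one item.

    Row ``j`` of the result is the sorted, duplicate-free union over every
    end position ``p`` in the parent's row ``j`` of the new item's positions
    ``q`` with ``p < q < p + G``.  All qualifying positions are retained:
    keeping only one successor per parent position can silently lose support
    for deeper extensions (see :func:`extend_matrix_min_only`).
    """
    rows: list[list[int]] = []
    for j, parent_row in enumerate(parent.rows, start=1):
        if not parent_row:
            rows.append([])
            continue
        out: set[int] = set()
        for p in parent_row:
            out.update(successors_in_window(index, item, j, p, G))
        rows.append(sorted(out))
    return CountingMatrix(rows)


def extend_matrix_min_only(index: PositionIndex, parent: CountingMatrix, item: str, G: int) -> CountingMatrix:
    """Deliberately incomplete variant of :func:`extend_matrix` that keeps only
    the minimum in-window successor per parent position.

    Exists solely as a regression foil: it demonstrates that min-only
    retention misses patterns whose later items need a non-minimal anchor
    (e.g. ``A*C*T`` on the single sequence ``ACCGT`` with ``G=3``).  Never
    used by :func:`mine`.
    """
    rows: list[list[int]] = []
    for j, parent_row in enumerate(parent.rows, start=1):
        out: set[int] = set()
        for p in parent_row:
            window = successors_in_window(index, item, j, p, G)
            if window:
                out.add(window[0])
        rows.append(sorted(out))
    return CountingMatrix(rows)


def support_of(matrix: CountingMatrix) -> int:
    """Number of non-empty rows: each sequence contributes at most one count
    no matter how many end positions its row holds."""
    return sum(1 for row in matrix.rows if row)


def mine(
    db: SequenceDatabase,
    params: MiningParams,
    sort: bool = False,
    _extend: Callable[[PositionIndex, CountingMatrix, str, int], CountingMatrix] = extend_matrix,
) -> list[MotifRecord]:
    """Mine every gapped pattern whose support meets the threshold.

    Builds the index once, then depth-first spells candidates in alphabet
    item order: each alphabet item seeds a length-1 candidate; a qualifying
    candidate is emitted and every one-item extension is tried recursively;
    a failing candidate is neither emitted nor extended (anti-monotone
    pruning).  Output is in DFS preorder, each qualifying pattern exactly
    once; ``sort=True`` re-sorts lexicographically by pattern string, then by
    descending support.
    """
    if db.N == 0:
        raise ValueError("cannot mine an empty database")
    threshold = resolve_threshold(params, db.N)
    if threshold > db.N:
        return []

    index = build_index(db)
    G = params.gap
    max_length = params.max_length if params.max_length is not None else math.inf
    results: list[MotifRecord] = []

    def emit(pattern: GappedPattern, matrix: CountingMatrix, support: int) -> None:
        if pattern.length < params.min_length:
            return
        record = MotifRecord(pattern, support)
        if params.report_positions:
            record.supporting_ids = [
                db.sequences[j].id for j, row in enumerate(matrix.rows) if row
            ]
            record.end_positions = CountingMatrix([list(r) for r in matrix.rows])
        results.append(record)

    def descend(pattern: GappedPattern, matrix: CountingMatrix) -> None:
        support = support_of(matrix)
        if support < threshold:
            return
        emit(pattern, matrix, support)
        if pattern.length >= max_length:
            return
        for item in db.alphabet:
            descend(pattern.extended(item), _extend(index, matrix, item, G))

    for item in db.alphabet:
        descend(GappedPattern((item,), G), initial_matrix(index, item))

    if sort:
        results.sort(key=lambda r: (str(r.pattern), -r.support))
    logger.info(
        "mined %d pattern(s) (N=%d, threshold=%d, G=%d, max length found=%d)",
        len(results), db.N, threshold, G,
        max((r.pattern.length for r in results), default=0),
    )
    return results


def write_motifs_tsv(
    records: list[MotifRecord],
    path: Union[str, Path, io.TextIOBase],
    N: int,
    positions_path: Union[str, Path, io.TextIOBase, None] = None,
) -> None:
    """Write the motif table: pattern, length, support, support_fraction
    (6 decimals).  When ``positions_path`` is given, a second TSV maps each
    pattern to its per-sequence end positions."""

    def _write(handle: io.TextIOBase) -> None:
        handle.write("pattern\tlength\tsupport\tsupport_fraction\n")
        for rec in records:
            handle.write(
                f"{rec.pattern}\t{rec.pattern.length}\t{rec.support}\t{rec.support / N:.6f}\n"
            )

    def _write_positions(handle: io.TextIOBase) -> None:
        handle.write("pattern\tsequence_id\tend_positions\n")
        for rec in records:
            if rec.end_positions is None:
                continue
            for sid, row in zip(rec.supporting_ids or [], (r for r in rec.end_positions.rows if r)):
                handle.write(f"{rec.pattern}\t{sid}\t{','.join(map(str, row))}\n")

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            _write(handle)
    else:
        _write(path)

    if positions_path is not None:
        if isinstance(positions_path, (str, Path)):
            with open(positions_path, "w", encoding="utf-8", newline="\n") as handle:
                _write_positions(handle)
        else:
            _write_positions(positions_path)
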