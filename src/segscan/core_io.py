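"""Alignment and interval containers plus FASTA / TSV readers and writers.

Every downstream stage (distance trees, selection statistics, the PHI test,
the cassette scan) consumes the :class:`Alignment` defined here.  Columns are
0-based throughout the package and intervals are half-open ``[start, end)``;
conversion to 1-based figure-style numbering happens only when reports are
rendered.

Gaps (``-``) and ``N`` are treated as missing data everywhere downstream
(pairwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTN-")
MISSING_CHARS = frozenset("N-")


class AlignmentShapeError(ValueError):
    """Rows of an alignment do not all have the same length."""


class DuplicateIdError(ValueError):
    """Two records in one alignment share an identifier."""


class EmptyInputError(ValueError):
    """An operation received no usable sequence data."""


class UnknownIdError(KeyError):
    """A requested identifier is not present in the alignment."""


@dataclass(frozen=True)
class ColumnInterval:
    """Half-open column interval ``[start, end)`` on an alignment."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, column: int) -> bool:
        return self.start <= column < self.end

    def overlaps(self, other: "ColumnInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def jaccard(self, other: "ColumnInterval") -> float:
        inter = max(0, min(self.end, other.end) - max(self.start, other.start))
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class VariantSite:
    """A column where a focal sequence differs from a background consensus.

    ``effect`` is one of ``synonymous``, ``non-synonymous``, ``non-coding``
    or ``indel``; ``non-coding`` is used exactly for columns outside the
    declared coding range.
    """

    column: int
    focal_state: str
    background_state: str
    effect: str

    def __post_init__(self) -> None:
        if self.focal_state == self.background_state:
            raise ValueError("focal and background state must differ")
        if self.effect not in ("synonymous", "non-synonymous", "non-coding", "indel"):
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences.

    Rows are uppercase strings over ``{A, C, G, T, N, -}`` of identical
    length ``L``.  ``frame_offset``, when set, is the 0-based column where
    codon position 1 of the reading frame begins (0, 1 or 2).
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    frame_offset: int | None = None

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise EmptyInputError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate identifiers: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal row lengths: {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentShapeError("alignment has zero columns")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - VALID_CHARS
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in {rid!r}")
        if self.frame_offset is not None and not (0 <= self.frame_offset < 3):
            raise ValueError("frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise UnknownIdError(seq_id) from None

    def subset(self, keep: Sequence[str]) -> "Alignment":
        """Restrict to the given identifiers, in the given order."""
        rows = tuple(self.row(i) for i in keep)
        return Alignment(tuple(keep), rows, self.frame_offset)

    def to_array(self) -> np.ndarray:
        """Rows as an (n, L) array of single characters (dtype ``<U1``)."""
        return np.array([list(r) for r in self.rows], dtype="<U1")

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the state is ``-`` or ``N``."""
        arr = self.to_array()
        return (arr == "-") | (arr == "N")


def alignment_from_array(
    ids: Sequence[str], arr: np.ndarray, frame_offset: int | None = None
) -> Alignment:
    rows = tuple("".join(r) for r in arr)
    return Alignment(tuple(ids), rows, frame_offset)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T").replace(".", "-")


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file.

    Rows are uppercased, ``U`` is mapped to ``T`` and identifiers are taken
    from the header up to the first whitespace (Biopython's convention).
    """
    if format != "fasta":
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"duplicate identifiers in {path}")
    rows = tuple(_normalize(str(r.seq)) for r in records)
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment as FASTA.

    Round-trips through :func:`read_alignment` exactly, with one documented
    lossy case: an identifier containing whitespace is truncated at its first
    whitespace on re-read.
    """
    if format != "fasta":
        raise ValueError(f"unsupported format {format!r}")
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


class Consensus(NamedTuple):
    sequence: str
    ambiguous: tuple[bool, ...]


#: fixed tie-break order for consensus calls
_BASE_ORDER = "ACGT"


def consensus(aln: Alignment, subset: Sequence[str] | None = None) -> Consensus:
    """Strict-majority consensus over a subset of rows.

    Per column the plurality nucleotide among non-missing states is taken;
    ties are resolved by the fixed order A < C < G < T and flagged in the
    ambiguity mask.  A column with no non-missing state yields ``N`` (also
    flagged).
    """
    ids = tuple(subset) if subset is not None else aln.ids
    if len(ids) == 0:
        raise EmptyInputError("empty subset for consensus")
    sub = aln.subset(ids)
    arr = sub.to_array()
    out = []
    flags = []
    for col in arr.T:
        counts = {b: int(np.sum(col == b)) for b in _BASE_ORDER}
        best = max(counts.values())
        if best == 0:
            out.append("N")
            flags.append(True)
            continue
        winners = [b for b in _BASE_ORDER if counts[b] == best]
        out.append(winners[0])
        flags.append(len(winners) > 1)
    return Consensus("".join(out), tuple(flags))


def variable_columns(aln: Alignment) -> list[int]:
    """Columns with at least two distinct non-missing states."""
    arr = aln.to_array()
    cols = []
    for j in range(aln.length):
        states = {c for c in arr[:, j] if c not in MISSING_CHARS}
        if len(states) >= 2:
            cols.append(j)
    return cols


INTERVAL_TSV_HEADER = "# id\tstart\tend (0-based, half-open)"


def write_intervals(rows: Iterable[tuple[str, ColumnInterval]], path) -> None:
    with open(path, "w") as fh:
        fh.write(INTERVAL_TSV_HEADER + "\n")
        for name, iv in rows:
            fh.write(f"{name}\t{iv.start}\t{iv.end}\n")


def read_intervals(path) -> list[tuple[str, ColumnInterval]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, start, end = line.split("\t")
            out.append((name, ColumnInterval(int(start), int(end))))
    return out
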