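"""Sequence records, 1-based closed intervals, alignments, and file I/O.

Every coordinate in this package is 1-based and fully closed, matching the
convention of printed protein spans ("118-140" covers 23 residues =
140 - 118 + 1).  Anything that needs another convention (e.g. Python
slicing) converts at the boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Letters accepted in a residue string: standard residues plus X (unknown).
ACCEPTED_AA = STANDARD_AA | {"X"}
GAP = "-"

__all__ = [
    "STANDARD_AA",
    "ACCEPTED_AA",
    "GAP",
    "ProteinRecord",
    "Interval",
    "AlignmentBlock",
    "interval_length",
    "merge_intervals",
    "project_interval_to_columns",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_tsv",
    "write_tsv",
]


class FastaError(ValueError):
    """Raised for malformed or invalid FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Residues are upper-cased on construction; only the 20 standard letters
    plus ``X`` (unknown residue) are accepted.  ``*`` (stop) and any other
    character are rejected — a stop codon in a protein string indicates an
    upstream parsing fault, not biology.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residue string")
        up = self.residues.upper()
        for pos, ch in enumerate(up, start=1):
            if ch not in ACCEPTED_AA:
                raise FastaError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, fully-closed residue interval. ``(5, 5)`` has length 1."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def positions(self) -> range:
        """All covered positions, ascending."""
        return range(self.start, self.end + 1)


def interval_length(iv: Interval) -> int:
    """Number of residues covered by ``iv`` (end - start + 1)."""
    return len(iv)


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or adjacent intervals into maximal runs."""
    out: list[Interval] = []
    for iv in sorted(ivs):
        if out and iv.start <= out[-1].end + 1:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


@dataclass
class AlignmentBlock:
    """An ordered set of gapped rows sharing one column count (gap ``-``).

    Ungapping any row reproduces the residues of its source record.
    Columns are addressed 1-based, like residue positions.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if not self.rows:
            raise ValueError("empty alignment")
        ncol = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ValueError(
                    f"row {rid!r} has {len(row)} columns, expected {ncol}"
                )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, top to bottom."""
        return "".join(row[col - 1] for row in self.rows)

    def subset_columns(self, columns: Sequence[int]) -> "AlignmentBlock":
        """New block keeping the given 1-based columns, in the given order."""
        rows = ["".join(row[c - 1] for c in columns) for row in self.rows]
        return AlignmentBlock(list(self.ids), rows)

    def records(self) -> list[ProteinRecord]:
        return [ProteinRecord(i, self.ungapped(i)) for i in self.ids]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))


def project_interval_to_columns(row: str, iv: Interval) -> Interval:
    """Map a residue interval of an ungapped row onto alignment columns.

    Returns the smallest 1-based column interval whose non-gap positions
    cover exactly residues ``iv.start..iv.end`` of ``row`` once gaps are
    removed.  For a gapless row this is the identity.
    """
    residue = 0
    first_col = last_col = None
    for col, ch in enumerate(row, start=1):
        if ch == GAP:
            continue
        residue += 1
        if residue == iv.start:
            first_col = col
        if residue == iv.end:
            last_col = col
            break
    if first_col is None or last_col is None:
        raise ValueError(
            f"interval ({iv.start}, {iv.end}) exceeds ungapped length {residue}"
        )
    return Interval(first_col, last_col)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[ProteinRecord]:
    """Read protein FASTA into records, preserving order.

    Wrapped sequence lines are concatenated.  Duplicate ids and non-amino
    characters are errors; with ``allow_gaps`` the gap character is kept
    (use :func:`read_alignment` for aligned input).
    """
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FastaError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    for rec in parsed:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if allow_gaps:
            seq = seq.replace(GAP, "")
        _validate_residues(rec.id, str(rec.seq), allow_gaps=allow_gaps)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(ProteinRecord(rec.id, seq, desc))
    return out


def _validate_residues(rid: str, seq: str, *, allow_gaps: bool) -> None:
    ok = ACCEPTED_AA | ({GAP} if allow_gaps else set())
    for pos, ch in enumerate(seq.upper(), start=1):
        if ch not in ok:
            raise FastaError(f"record {rid!r}: invalid residue {ch!r} at position {pos}")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, *, width: int = 60) -> None:
    """Write records as FASTA, wrapping at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> AlignmentBlock:
    """Read an aligned FASTA (gap ``-``) into an :class:`AlignmentBlock`."""
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FastaError(f"{path}: no FASTA records found")
    ids, rows = [], []
    for rec in parsed:
        seq = str(rec.seq).upper()
        _validate_residues(rec.id, seq, allow_gaps=True)
        ids.append(rec.id)
        rows.append(seq)
    return AlignmentBlock(ids, rows)


def write_alignment(block: AlignmentBlock, path: str | Path, *, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in block:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    """Tab-delimited UTF-8 table with a header row; '#' lines are comments."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def write_tsv(df: pd.DataFrame, path: str | Path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
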