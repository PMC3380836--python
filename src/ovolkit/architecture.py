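"""Per-protein domain architectures: N-extension / C2H2-tetrad core /
C-extension, plus the cross-lineage summary table.

The conserved core of an OVOL-type protein is the span from the start of
zinc-finger motif I to the end of motif IV, inclusive of the short
inter-motif linkers.  Everything N-terminal of the core is the
N-extension, everything C-terminal the C-extension; in most lineages these
extensions are long, intrinsically disordered, and non-homologous across
lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import Interval, ProteinRecord
from .disorder import RegionAnnotation
from .patterns import MotifMatch, PatternSpec, rightmost_tetrad, scan

__all__ = ["DomainArchitecture", "TetradNotFoundError", "build_architecture", "summarize_architectures"]


class TetradNotFoundError(ValueError):
    """No C2H2 tetrad found; carries the partial match list."""

    def __init__(self, sequence_id: str, matches: Sequence[MotifMatch]) -> None:
        super().__init__(
            f"no C2H2 tetrad found in {sequence_id!r} "
            f"({len(matches)} motif match(es))"
        )
        self.matches = list(matches)


@dataclass
class DomainArchitecture:
    """A protein partitioned into N-extension, tetrad core, C-extension."""

    sequence_id: str
    total_length: int
    tetrad: tuple[MotifMatch, MotifMatch, MotifMatch, MotifMatch]
    core: Interval
    id_regions: list[RegionAnnotation] = field(default_factory=list)
    lineage: str = ""

    @property
    def n_extension_len(self) -> int:
        return self.core.start - 1

    @property
    def c_extension_len(self) -> int:
        return self.total_length - self.core.end

    @property
    def extension_side(self) -> str:
        """'N-only', 'C-only', 'both' or 'none'."""
        n, c = self.n_extension_len > 0, self.c_extension_len > 0
        return {(True, True): "both", (True, False): "N-only",
                (False, True): "C-only", (False, False): "none"}[(n, c)]

    def classify_region(self, ann: RegionAnnotation) -> str:
        """Locate an annotation relative to the core ('n-extension',
        'core', 'c-extension', or 'spanning')."""
        if ann.iv.end < self.core.start:
            return "n-extension"
        if ann.iv.start > self.core.end:
            return "c-extension"
        if ann.iv.start >= self.core.start and ann.iv.end <= self.core.end:
            return "core"
        return "spanning"


def build_architecture(
    seq: ProteinRecord,
    pat: PatternSpec,
    annotations: Iterable[RegionAnnotation] = (),
    *,
    max_linker: int = 20,
    lineage: str = "",
) -> DomainArchitecture:
    """Scan a protein for its C2H2 tetrad and partition it around the core.

    All overlapping matches are enumerated and the C-terminal-most
    compact tetrad is selected, since the conserved tetrad of this family
    sits at the C-terminal end; this is robust to chance upstream
    cysteines that would derail a greedy left-to-right cover.
    Raises :class:`TetradNotFoundError` (carrying the partial match list)
    when no tetrad exists.
    """
    matches = scan(seq, pat, "all-overlapping")
    tetrad = rightmost_tetrad(matches, max_linker)
    if tetrad is None:
        raise TetradNotFoundError(seq.id, matches)
    core = Interval(tetrad[0].iv.start, tetrad[3].iv.end)
    own = [a for a in annotations if a.sequence_id == seq.id]
    return DomainArchitecture(seq.id, len(seq), tetrad, core, own, lineage)


def summarize_architectures(archs: Sequence[DomainArchitecture]) -> pd.DataFrame:
    """One row per protein plus a trailing min-max length-range row.

    Columns: lineage, seq_id, total_length, n_extension_len,
    c_extension_len, extension_side, n_id_patches, dominant_residues
    (comma-joined dominant residues of x-rich patches).
    """
    if not archs:
        raise ValueError("no architectures to summarize")
    rows = []
    for a in archs:
        xrich = [r for r in a.id_regions if r.kind == "x-rich"]
        dominant = ",".join(sorted({r.detail.split(":")[0] for r in xrich if r.detail}))
        rows.append(
            {
                "lineage": a.lineage or a.sequence_id,
                "seq_id": a.sequence_id,
                "total_length": a.total_length,
                "n_extension_len": a.n_extension_len,
                "c_extension_len": a.c_extension_len,
                "extension_side": a.extension_side,
                "n_id_patches": len(xrich),
                "dominant_residues": dominant,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["length_range"] = (int(df.total_length.min()), int(df.total_length.max()))
    return df
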