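"""Micro-synteny comparison of focal-gene loci.

A locus is described by a gene-order table: one row per gene on a contig,
with rank (position in gene order), gene id, family id and strand, and a
flag marking the focal gene.  Orthologous loci in two genomes share the
same flanking marker genes; paralogous loci born of a segmental
("fragmental") duplication share homologous-but-distinct markers — members
of the same gene family (e.g. BANF1 at one locus, BANF2 at the other).
The duplication-then-loss pattern of a whole-genome duplication leaves the
focal gene only at the duplicated locus, while the original locus retains
the ancestral markers (plus one member of a duplicated marker-family pair,
e.g. AKT2a vs AKT2b).

Marker *presence* is what is scored; order and strand are recorded and
reported but not scored, and colinearity statistics are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core_io import read_tsv, write_tsv

__all__ = [
    "Marker",
    "LocusCard",
    "FamilyMap",
    "LocusCall",
    "read_locus_table",
    "read_family_map",
    "shared_markers",
    "classify_locus_pair",
    "detect_duplication_loss",
    "calls_to_frame",
]


@dataclass(frozen=True)
class Marker:
    """One flanking gene of a locus."""

    gene_id: str
    family_id: str
    strand: str = "+"
    side: str = "."        # 'left' / 'right' of the focal position, '.' if unknown
    rank_distance: int = 1  # gene-order distance from the focal position

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError(f"marker {self.gene_id!r}: empty family id")
        if self.rank_distance < 1:
            raise ValueError(f"marker {self.gene_id!r}: rank distance must be >= 1")


@dataclass
class LocusCard:
    """A focal gene (possibly lost) plus its ordered flanking markers."""

    genome: str
    contig: str
    focal_gene: str | None
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        for side in ("left", "right"):
            ranks = [m.rank_distance for m in self.markers if m.side == side]
            if ranks != sorted(ranks) or len(ranks) != len(set(ranks)):
                raise ValueError(
                    f"{self.genome}/{self.contig}: {side} ranks must be "
                    "strictly increasing"
                )

    @property
    def label(self) -> str:
        return f"{self.genome}:{self.contig}"

    def marker_genes(self, window: int | None = None) -> set[str]:
        return {
            m.gene_id
            for m in self.markers
            if window is None or m.rank_distance <= window
        }

    def marker_families(self, window: int | None = None) -> set[str]:
        return {
            m.family_id
            for m in self.markers
            if window is None or m.rank_distance <= window
        }

    def swap_sides(self) -> "LocusCard":
        """Mirror left/right labels (loci appear in either orientation)."""
        flip = {"left": "right", "right": "left", ".": "."}
        return LocusCard(
            self.genome,
            self.contig,
            self.focal_gene,
            [
                Marker(m.gene_id, m.family_id, m.strand, flip[m.side], m.rank_distance)
                for m in self.markers
            ],
        )


class FamilyMap(dict):
    """gene id -> family id; unknown genes map to themselves (singletons)."""

    def family(self, gene_id: str) -> str:
        return self.get(gene_id, gene_id)


@dataclass
class LocusCall:
    """The verdict on a pair of loci."""

    card_a: LocusCard
    card_b: LocusCard
    shared_genes: set[str]
    shared_families: set[str]
    verdict: str  # orthologous | paralogous-duplication | unrelated | duplicate-retained-original-lost


def read_locus_table(path: str | Path) -> dict[str, LocusCard]:
    """Read a gene-order TSV into cards keyed by 'genome:contig'.

    Columns: genome, contig, rank, gene_id, family_id, strand, is_focal.
    Rank is the gene-order index along the contig; the focal row (is_focal
    truthy) anchors sides and rank distances.  A focal row with an empty
    gene_id marks a focal *position* whose gene was lost.
    """
    df = read_tsv(path)
    required = {"genome", "contig", "rank", "gene_id", "family_id", "strand", "is_focal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cards: dict[str, LocusCard] = {}
    for (genome, contig), grp in df.groupby(["genome", "contig"], sort=False):
        grp = grp.assign(rank=grp["rank"].astype(int)).sort_values("rank")
        focal_rows = grp[grp["is_focal"].isin({"1", "true", "True", "yes"})]
        if len(focal_rows) > 1:
            raise ValueError(f"{path}: multiple focal rows for {genome}/{contig}")
        focal_gene = None
        focal_rank = None
        if len(focal_rows) == 1:
            focal_rank = int(focal_rows.iloc[0]["rank"])
            fg = focal_rows.iloc[0]["gene_id"].strip()
            focal_gene = fg or None
        markers = []
        for _, r in grp.iterrows():
            rank = int(r["rank"])
            if focal_rank is not None and rank == focal_rank:
                continue
            if focal_rank is None:
                side, dist = ".", max(1, rank)
            else:
                side = "left" if rank < focal_rank else "right"
                dist = abs(rank - focal_rank)
            markers.append(Marker(r["gene_id"], r["family_id"], r["strand"] or "+", side, dist))
        markers.sort(key=lambda m: (m.side, m.rank_distance))
        card = LocusCard(str(genome), str(contig), focal_gene, markers)
        cards[card.label] = card
    return cards


def read_family_map(path: str | Path) -> FamilyMap:
    df = read_tsv(path)
    if not {"gene_id", "family_id"} <= set(df.columns):
        raise ValueError(f"{path}: need gene_id and family_id columns")
    return FamilyMap(zip(df["gene_id"], df["family_id"]))


def shared_markers(
    a: LocusCard,
    b: LocusCard,
    window: int = 8,
    fam: FamilyMap | None = None,
) -> tuple[set[str], set[str]]:
    """Marker gene ids and family ids shared by two loci within ``window``
    rank distance of the focal position."""
    if window < 1:
        raise ValueError("window must be >= 1")
    fam = fam or FamilyMap()
    genes_a, genes_b = a.marker_genes(window), b.marker_genes(window)
    fams_a = {fam.family(g) for g in genes_a}
    fams_b = {fam.family(g) for g in genes_b}
    return genes_a & genes_b, fams_a & fams_b


def classify_locus_pair(
    a: LocusCard,
    b: LocusCard,
    fam: FamilyMap | None = None,
    min_ortho: int = 3,
    min_para: int = 2,
    window: int = 8,
) -> LocusCall:
    """Orthologous / paralogous-duplication / unrelated verdict on a locus pair.

    Orthologous loci share at least ``min_ortho`` identical marker genes;
    a segmental duplication is called when fewer identical genes but at
    least ``min_para`` marker *families* are shared (homologous flanking
    pairs like BANF1/BANF2); otherwise the loci are unrelated.
    """
    if min_ortho < 1 or min_para < 1:
        raise ValueError("thresholds must be >= 1")
    genes, families = shared_markers(a, b, window, fam)
    if len(genes) >= min_ortho:
        verdict = "orthologous"
    elif len(families) >= min_para:
        verdict = "paralogous-duplication"
    else:
        verdict = "unrelated"
    return LocusCall(a, b, genes, families, verdict)


def detect_duplication_loss(
    original: LocusCard,
    duplicated: LocusCard,
    reference: LocusCard,
    fam: FamilyMap | None = None,
    min_ortho: int = 3,
    window: int = 8,
) -> LocusCall:
    """Detect the duplicate-retained/original-lost pattern.

    ``original`` is a locus lacking the focal gene; ``duplicated`` carries
    it; ``reference`` is a focal-bearing locus from another genome.  The
    verdict is ``duplicate-retained-original-lost`` when the original
    locus still shares >= ``min_ortho`` markers with the reference (so it
    is the ancestral locus) and the original and duplicated loci share at
    least one paralogous marker-family pair (distinct genes, same family —
    the trace of the duplication).  Otherwise ``unrelated``.
    """
    if original.focal_gene is not None:
        raise ValueError("the original locus must lack its focal gene")
    if duplicated.focal_gene is None:
        raise ValueError("the duplicated locus must carry the focal gene")
    fam = fam or FamilyMap()
    ref_genes, _ = shared_markers(original, reference, window, fam)
    genes_o = original.marker_genes(window)
    genes_d = duplicated.marker_genes(window)
    shared_gene_ids = genes_o & genes_d
    paralog_families = {
        f
        for f in ({fam.family(g) for g in genes_o} & {fam.family(g) for g in genes_d})
        if not any(fam.family(g) == f for g in shared_gene_ids)
    }
    if len(ref_genes) >= min_ortho and paralog_families:
        verdict = "duplicate-retained-original-lost"
    else:
        verdict = "unrelated"
    return LocusCall(original, duplicated, shared_gene_ids, paralog_families, verdict)


def calls_to_frame(calls: Iterable[LocusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_a": c.card_a.label,
                "locus_b": c.card_b.label,
                "focal_a": c.card_a.focal_gene or ".",
                "focal_b": c.card_b.focal_gene or ".",
                "shared_genes": ",".join(sorted(c.shared_genes)) or ".",
                "n_shared_genes": len(c.shared_genes),
                "shared_families": ",".join(sorted(c.shared_families)) or ".",
                "n_shared_families": len(c.shared_families),
                "verdict": c.verdict,
            }
            for c in calls
        ]
    )
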