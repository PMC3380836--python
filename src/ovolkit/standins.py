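"""Synthetic stand-in proteins for database reference sequences.

The real OVOL proteins live in genome databases that this package never
downloads from.  These constructors build *synthetic* stand-ins whose
published architecture — motif coordinates, overall length, inter-motif
linkers, compositional bias of the extensions — matches the literature
values for the corresponding protein, while the filler residues are an
arbitrary deterministic cycle.  They are suitable for exercising and
validating coordinate arithmetic, motif scanning, and architecture
partitioning; they are NOT the real sequences.

Design constraints baked into the constructors:

* cysteine never occurs outside the intended zinc-finger anchors, and
  motif interiors avoid C/H fillers, so a C2H2 scan finds exactly the
  four intended motifs and nothing else;
* each motif satisfies the generic C2H2 pattern
  ``C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H`` with the unique
  anchor spacing that reproduces its published span length.
"""

from __future__ import annotations

from itertools import cycle

from .core_io import Interval, ProteinRecord

__all__ = [
    "synthetic_ovol1_standin",
    "synthetic_ovob_standin",
    "HUMAN_OVOL1_MOTIF_SPANS",
    "OVOB_MOTIF_SPANS",
    "OVOB_ID_SPANS",
]

#: Published human OVOL1 C2H2 motif spans (23, 23, 24, 24 aa).
HUMAN_OVOL1_MOTIF_SPANS = [Interval(118, 140), Interval(146, 168), Interval(174, 197), Interval(213, 236)]
#: Published fruit-fly OVO-B C2H2 motif spans (23, 23, 24, 24 aa).
OVOB_MOTIF_SPANS = [Interval(1197, 1219), Interval(1225, 1247), Interval(1253, 1276), Interval(1292, 1315)]
#: Published OVO-B single-residue-bias regions (dominant residue, span).
#: The published His-rich span (645-665, stated "39 aa") is internally
#: inconsistent and deliberately omitted.
OVOB_ID_SPANS = [
    ("E", Interval(196, 239)),    # Glu-rich, 44 aa
    ("P", Interval(309, 342)),    # Pro-rich, 34 aa
    ("G", Interval(448, 618)),    # Gly-rich, 171 aa
    ("N", Interval(620, 660)),    # Asn-rich, 41 aa
    ("Q", Interval(837, 1158)),   # Gln-rich, 322 aa
    ("A", Interval(1001, 1059)),  # Ala-rich, 59 aa (nested in the Gln region)
    ("S", Interval(1025, 1045)),  # Ser-rich, 21 aa (nested in the Gln region)
]

_FILLER = "QSPGLAETKRVNDMIW"   # no C, no H, no F
_MOTIF_FILLER = "SPGLAETKRVND"  # additionally varied; no C/H/F


def _filled(length: int, source: str) -> list[str]:
    it = cycle(source)
    return [next(it) for _ in range(length)]


def _motif(span_len: int) -> list[str]:
    """A C2H2 motif of the requested span (23 or 24 aa).

    23 aa: C-x(2)-C-x(3)-F-x(8)-H-x(5)-H; 24 aa: C-x(3)-C-x(3)-F-x(8)-H-x(5)-H.
    Both satisfy the generic C2H2 pattern; fillers carry no C/H/F.
    """
    if span_len == 23:
        anchors = {1: "C", 4: "C", 8: "F", 17: "H", 23: "H"}
    elif span_len == 24:
        anchors = {1: "C", 5: "C", 9: "F", 18: "H", 24: "H"}
    else:
        raise ValueError(f"unsupported motif span {span_len}")
    fill = cycle(_MOTIF_FILLER)
    return [anchors.get(i) or next(fill) for i in range(1, span_len + 1)]


def _assemble(total: int, motif_spans: list[Interval], rich_spans, rec_id: str, desc: str) -> ProteinRecord:
    chars = _filled(total, _FILLER)
    for residue, iv in rich_spans:
        for pos in iv.positions():
            # 4-of-5 dominance keeps the region detectably biased while
            # letting nested regions coexist
            chars[pos - 1] = residue if (pos - iv.start) % 5 != 4 else "L"
    for iv in motif_spans:
        chars[iv.start - 1 : iv.end] = _motif(len(iv))
    return ProteinRecord(rec_id, "".join(chars), desc)


def synthetic_ovol1_standin() -> ProteinRecord:
    """Synthetic 267-aa stand-in for the human OVOL1 protein.

    Motifs sit at the published spans 118-140, 146-168, 174-197 and
    213-236 (23/23/24/24 aa; inter-motif linkers 5, 5, 15); the remainder
    is deterministic filler.  Synthetic: not the database sequence.
    """
    return _assemble(
        267, HUMAN_OVOL1_MOTIF_SPANS, [],
        "OVOL1_HUMAN_SYNTHETIC", "synthetic stand-in, published motif coordinates"
    )


def synthetic_ovob_standin() -> ProteinRecord:
    """Synthetic 1351-aa stand-in for the fruit-fly OVO-B isoform.

    Motifs at the published spans 1197-1219 .. 1292-1315; the N-terminal
    extension carries single-residue-biased segments at the published
    spans (Glu/Pro/Gly/Asn/Gln/Ala/Ser-rich).  Synthetic: not the
    database sequence.
    """
    return _assemble(
        1351, OVOB_MOTIF_SPANS, OVOB_ID_SPANS,
        "OVOB_DROME_SYNTHETIC", "synthetic stand-in, published motif and bias coordinates"
    )
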