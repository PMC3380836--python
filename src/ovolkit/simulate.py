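"""Synthetic OVOL-like protein families with truth annotations.

The generator emulates the statistical structure the downstream analysis
assumes: a slowly-evolving conserved core of four tandem C2H2 zinc-finger
motifs, flanked by fast-evolving, compositionally-biased, intrinsically
disordered (ID) N/C-terminal extensions of 100-1000 residues.  Every
sequence descends from a common ancestor along a guide tree (a star tree
by default); homology is tracked site-by-site, so a gap-true multiple
alignment and exact truth annotations (motif and core intervals, ID
regions) come out alongside the FASTA.

Model choices, stated plainly:

* substitutions replace a residue uniformly among the other 19 (no
  empirical exchangeability matrix — the downstream statistics are
  distance-based, not model-based);
* the eight Cys/His anchors of the tetrad are hard-invariant by default
  (guaranteeing motif detectability, so pipeline failures indicate bugs
  rather than simulation luck); the set position after the second Cys is
  constrained to the {F,W,S,G,A,T} members the consensus allows;
* ID extensions are drawn once at the root and then evolve per branch at
  ``p_id`` with indels (geometric lengths, mean 3, insertion and deletion
  equiprobable), so they remain alignable while diverging fast;
* with probability ``bias_probability`` an ID segment is compositionally
  biased: a dominant residue appears at frequency ``bias_strength`` and
  substitutions/insertions within the segment redraw from the same
  composition, keeping the bias stationary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .core_io import AlignmentBlock, Interval, ProteinRecord
from .disorder import DisorderTrack, RegionAnnotation

__all__ = ["SimulationConfig", "TruthSet", "FamilyResult", "simulate_family", "emit_disorder_tracks"]

AA = sorted("ACDEFGHIKLMNPQRSTVWY")
SET_POSITION_MEMBERS = list("FWSGAT")  # allowed states of the post-Cys set position
# residues used for neutral template filler: no C/H (would seed spurious
# zinc-finger anchors), no F (reserved for the set position)
FILLER = [a for a in AA if a not in "CHF"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated family.

    ``p_core``/``p_id`` are per-site substitution probabilities per unit
    branch length for core and ID sites (0.02 and 0.4 by default: the core
    diverges slowly, extensions are close to saturation across the family).
    ``extension_sides`` is one of 'N', 'C', 'both', 'none' applied to every
    lineage, or a per-taxon sequence thereof.  ``guide_tree`` is a Newick
    string; when absent a star tree over ``n_taxa`` leaves with unit branch
    lengths is used.
    """

    n_taxa: int = 6
    seed: int = 0
    p_core: float = 0.02
    p_id: float = 0.4
    id_length_range: tuple[int, int] = (100, 1000)
    extension_sides: str | Sequence[str] = "N"
    bias_probability: float = 0.5
    bias_strength: float = 0.5
    indel_rate: float = 0.02
    indel_mean_len: float = 3.0
    anchors_invariant: bool = True
    linker_lengths: tuple[int, int, int] = (5, 5, 15)
    guide_tree: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_core", "p_id", "bias_probability", "bias_strength", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_core > self.p_id:
            raise ValueError("p_core must not exceed p_id")
        lo, hi = self.id_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid id_length_range")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")

    def side_for(self, taxon_index: int) -> str:
        if isinstance(self.extension_sides, str):
            return self.extension_sides
        return self.extension_sides[taxon_index % len(self.extension_sides)]


@dataclass
class TruthSet:
    """Ground truth for one simulated family."""

    motifs: dict[str, list[Interval]]          # 4 motif intervals per taxon
    cores: dict[str, Interval]                 # motif-I-start .. motif-IV-end
    id_regions: list[RegionAnnotation]         # true disordered segments
    sides: dict[str, str]                      # simulated extension side
    tree_newick: str


@dataclass
class FamilyResult:
    """Sequences, truth, and the gap-true alignment of one simulation."""

    records: list[ProteinRecord]
    truth: TruthSet
    alignment: AlignmentBlock
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        from .core_io import write_alignment, write_fasta
        from .disorder import write_annotations

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "family.fasta")
        write_alignment(self.alignment, outdir / "family.aln.fasta")
        write_annotations(self.truth.id_regions, outdir / "truth_id_regions.tsv")
        (outdir / "guide_tree.nwk").write_text(self.truth.tree_newick + "\n")


# --- internal site bookkeeping ---------------------------------------------

_CAT_ANCHOR = 0   # invariant C/H of the tetrad
_CAT_SET = 1      # the [FWsgat] position
_CAT_CORE = 2     # other core sites (motif interiors + linkers)
_CAT_ID = 3       # extension sites


class _SiteRegistry:
    """Allocates site ids and records category / motif / segment metadata."""

    def __init__(self) -> None:
        self.category: list[int] = []
        self.motif: list[int] = []      # 1..4 inside a motif, 0 otherwise
        self.segment: list[int] = []    # ID segment id, -1 otherwise

    def new(self, category: int, motif: int = 0, segment: int = -1) -> int:
        self.category.append(category)
        self.motif.append(motif)
        self.segment.append(segment)
        return len(self.category) - 1


def _motif_template(rng: np.random.Generator, reg: _SiteRegistry, motif_no: int,
                    h_gap: int) -> list[tuple[int, str]]:
    """One C2H2 template: C-x(2)-C-x(3)-[F...]-x(8)-H-x(h_gap)-H."""
    sites: list[tuple[int, str]] = []

    def add(cat: int, residue: str) -> None:
        sites.append((reg.new(cat, motif=motif_no), residue))

    add(_CAT_ANCHOR, "C")
    for _ in range(2):
        add(_CAT_CORE, rng.choice(FILLER))
    add(_CAT_ANCHOR, "C")
    for _ in range(3):
        add(_CAT_CORE, rng.choice(FILLER))
    add(_CAT_SET, "F")
    for _ in range(8):
        add(_CAT_CORE, rng.choice(FILLER))
    add(_CAT_ANCHOR, "H")
    for _ in range(h_gap):
        add(_CAT_CORE, rng.choice(FILLER))
    add(_CAT_ANCHOR, "H")
    return sites


def _segment_composition(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Residue distribution of one ID segment (possibly single-residue biased)."""
    if rng.random() < cfg.bias_probability:
        dominant = rng.integers(len(AA))
        probs = np.full(len(AA), (1.0 - cfg.bias_strength) / (len(AA) - 1))
        probs[dominant] = cfg.bias_strength
    else:
        probs = np.full(len(AA), 1.0 / len(AA))
    return probs


def _draw_residue(rng: np.random.Generator, probs: np.ndarray, not_equal: str | None = None) -> str:
    for _ in range(64):
        r = AA[rng.choice(len(AA), p=probs)]
        if r != not_equal:
            return r
    # effectively-degenerate composition: fall back to any other residue
    others = [a for a in AA if a != not_equal]
    return str(rng.choice(others))


def simulate_family(config: SimulationConfig) -> FamilyResult:
    """Simulate one protein family along the guide tree; deterministic for
    a fixed config (the seed covers every random draw)."""
    rng = np.random.default_rng(config.seed)
    reg = _SiteRegistry()
    segments: dict[int, np.ndarray] = {}

    # --- ancestor: [N-ext] core(tetrad + linkers) [C-ext] ---
    core_sites: list[tuple[int, str]] = []
    for motif_no, h_gap in enumerate((3, 3, 4, 4), start=1):
        core_sites.extend(_motif_template(rng, reg, motif_no, h_gap))
        if motif_no < 4:
            for _ in range(config.linker_lengths[motif_no - 1]):
                core_sites.append((reg.new(_CAT_CORE), rng.choice(FILLER)))

    def make_extension(segment_id: int) -> list[tuple[int, str]]:
        lo, hi = config.id_length_range
        length = int(rng.integers(lo, hi + 1))
        probs = _segment_composition(rng, config)
        segments[segment_id] = probs
        return [
            (reg.new(_CAT_ID, segment=segment_id), _draw_residue(rng, probs))
            for _ in range(length)
        ]

    n_ext = make_extension(0)
    c_ext = make_extension(1)
    root_seq: list[tuple[int, str]] = n_ext + core_sites + c_ext
    master_order: list[int] = [sid for sid, _ in root_seq]

    # --- guide tree ---
    if config.guide_tree:
        tree = TreeNode.read(_io.StringIO(config.guide_tree))
        leaves = list(tree.tips())
        taxa = [leaf.name or f"t{i+1}" for i, leaf in enumerate(leaves)]
    else:
        taxa = [f"t{i+1}" for i in range(config.n_taxa)]
        newick = "(" + ",".join(f"{t}:1" for t in taxa) + ");"
        tree = TreeNode.read(_io.StringIO(newick))
    tree_newick = str(tree).strip()

    sides = {t: config.side_for(i) for i, t in enumerate(taxa)}

    def evolve_branch(seq: list[tuple[int, str]], length: float) -> list[tuple[int, str]]:
        p_scale = lambda p: 1.0 - (1.0 - p) ** length if length != 1.0 else p
        p_core = p_scale(config.p_core)
        p_id = p_scale(config.p_id)
        p_indel = p_scale(config.indel_rate)
        out: list[tuple[int, str]] = []
        pending_deletion = 0  # remaining sites of a geometric-length deletion
        for sid, residue in seq:
            cat = reg.category[sid]
            if pending_deletion and cat == _CAT_ID:
                pending_deletion -= 1
                continue
            if cat == _CAT_ANCHOR:
                if not config.anchors_invariant and rng.random() < p_core:
                    residue = _draw_residue(rng, np.full(len(AA), 1 / len(AA)), residue)
                out.append((sid, residue))
                continue
            if cat == _CAT_SET:
                if rng.random() < p_core:
                    others = [m for m in SET_POSITION_MEMBERS if m != residue]
                    residue = str(rng.choice(others))
                out.append((sid, residue))
                continue
            if cat == _CAT_CORE:
                if rng.random() < p_core:
                    residue = _draw_residue(rng, np.full(len(AA), 1 / len(AA)), residue)
                out.append((sid, residue))
                continue
            # ID site: substitution, then possible deletion / insertion
            seg = reg.segment[sid]
            probs = segments[seg]
            if rng.random() < p_id:
                residue = _draw_residue(rng, probs, residue)
            r = rng.random()
            if r < p_indel / 2.0:
                # deletion of a geometric-length run starting here
                pending_deletion = int(rng.geometric(1.0 / config.indel_mean_len)) - 1
                continue
            out.append((sid, residue))
            if r >= p_indel / 2.0 and r < p_indel:
                ins_len = int(rng.geometric(1.0 / config.indel_mean_len))
                anchor_idx = master_order.index(sid)
                for k in range(ins_len):
                    new_sid = reg.new(_CAT_ID, segment=seg)
                    master_order.insert(anchor_idx + 1 + k, new_sid)
                    out.append((new_sid, _draw_residue(rng, probs)))
        return out

    def drop_sides(seq: list[tuple[int, str]], side: str) -> list[tuple[int, str]]:
        keep_n = side in ("N", "both")
        keep_c = side in ("C", "both")
        out = []
        for sid, residue in seq:
            if reg.category[sid] == _CAT_ID:
                if reg.segment[sid] == 0 and not keep_n:
                    continue
                if reg.segment[sid] == 1 and not keep_c:
                    continue
            out.append((sid, residue))
        return out

    leaf_seqs: dict[str, list[tuple[int, str]]] = {}

    def recurse(node: TreeNode, seq: list[tuple[int, str]]) -> None:
        for child in node.children:
            length = child.length if child.length is not None else 1.0
            child_seq = evolve_branch(seq, float(length))
            if child.is_tip():
                leaf_seqs[child.name] = drop_sides(child_seq, sides[child.name])
            else:
                recurse(child, child_seq)

    recurse(tree, root_seq)

    # --- assemble outputs ---
    records: list[ProteinRecord] = []
    motifs: dict[str, list[Interval]] = {}
    cores: dict[str, Interval] = {}
    id_regions: list[RegionAnnotation] = []
    order_index = {sid: i for i, sid in enumerate(master_order)}
    for taxon in taxa:
        seq = sorted(leaf_seqs[taxon], key=lambda t: order_index[t[0]])
        leaf_seqs[taxon] = seq
        residues = "".join(r for _, r in seq)
        records.append(ProteinRecord(taxon, residues))
        motif_spans: dict[int, list[int]] = {}
        seg_runs: list[tuple[int, int, int]] = []  # (segment, start, end)
        for pos, (sid, _) in enumerate(seq, start=1):
            m = reg.motif[sid]
            if m:
                motif_spans.setdefault(m, []).append(pos)
            seg = reg.segment[sid]
            if seg >= 0:
                if seg_runs and seg_runs[-1][0] == seg and seg_runs[-1][2] == pos - 1:
                    seg_runs[-1] = (seg, seg_runs[-1][1], pos)
                else:
                    seg_runs.append((seg, pos, pos))
        motifs[taxon] = [
            Interval(min(motif_spans[m]), max(motif_spans[m])) for m in sorted(motif_spans)
        ]
        cores[taxon] = Interval(motifs[taxon][0].start, motifs[taxon][-1].end)
        for seg, s, e in seg_runs:
            id_regions.append(
                RegionAnnotation(taxon, Interval(s, e), "disordered", f"segment{seg}")
            )

    rows = []
    for taxon in taxa:
        present = {sid: r for sid, r in leaf_seqs[taxon]}
        rows.append("".join(present.get(sid, "-") for sid in master_order))
    # drop columns that are gaps in every row (sites extinct in all leaves)
    keep = [c for c in range(len(master_order)) if any(row[c] != "-" for row in rows)]
    rows = ["".join(row[c] for c in keep) for row in rows]
    alignment = AlignmentBlock(list(taxa), rows)

    truth = TruthSet(motifs, cores, id_regions, sides, tree_newick)
    return FamilyResult(records, truth, alignment, config)


def emit_disorder_tracks(
    result: FamilyResult,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> dict[str, DisorderTrack]:
    """Per-taxon disorder tracks consistent with the simulation truth.

    Scores are 0.9 (inside true ID regions) or 0.1 (elsewhere) plus
    Gaussian noise of ``noise_sd``, clamped to [0, 1]; states follow the
    0.5 threshold.  With ``noise_sd = 0`` the called regions reproduce the
    truth exactly.
    """
    rng = np.random.default_rng(seed)
    by_taxon: dict[str, list[RegionAnnotation]] = {}
    for ann in result.truth.id_regions:
        by_taxon.setdefault(ann.sequence_id, []).append(ann)
    tracks: dict[str, DisorderTrack] = {}
    for rec in result.records:
        scores = np.full(len(rec), 0.1)
        for ann in by_taxon.get(rec.id, []):
            scores[ann.iv.start - 1 : ann.iv.end] = 0.9
        if noise_sd > 0:
            scores = scores + rng.normal(0.0, noise_sd, size=scores.shape)
        scores = np.clip(scores, 0.0, 1.0)
        tracks[rec.id] = DisorderTrack(rec.id, scores, scores >= 0.5, 0.5, rec.residues)
    return tracks
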