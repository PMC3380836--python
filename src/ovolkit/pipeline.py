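"""End-to-end analysis pipeline: motifs -> architecture -> disorder ->
partitioned divergence -> tree (-> synteny), with file artifacts and a
machine-readable JSON summary.

Every stage writes its TSV artifact into the output directory; a MANIFEST
file records which stages completed, so a failed run leaves interpretable
partial output.  Runs are deterministic for a fixed config (the seed
covers simulation, bootstrap, and permutation draws).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .architecture import TetradNotFoundError, build_architecture, summarize_architectures
from .core_io import AlignmentBlock, ProteinRecord, read_alignment, read_fasta, write_tsv
from .disorder import (
    RegionAnnotation,
    call_disordered_regions,
    find_bias_patches,
    parse_disorder_table,
    write_annotations,
)
from .divergence import compare_partitions, distance_matrix, nj_tree
from .patterns import PS00028, matches_to_frame, parse_pattern, scan
from .simulate import SimulationConfig, emit_disorder_tracks, simulate_family
from .synteny import calls_to_frame, classify_locus_pair, read_family_map, read_locus_table

log = logging.getLogger("ovolkit")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    outdir: str = "ovolkit_out"
    seed: int = 0
    # inputs: either a FASTA/alignment pair, or a simulation
    fasta: str | None = None
    alignment: str | None = None
    disorder_tables: list[str] = field(default_factory=list)
    simulate: bool = False
    simulation: dict[str, Any] = field(default_factory=dict)
    # analysis parameters
    pattern: str = PS00028
    max_linker: int = 20
    min_disorder_len: int = 5
    bias_window: int = 20
    bias_min_frac: float = 0.35
    rule_frac: float = 0.5
    # optional synteny inputs
    loci_table: str | None = None
    family_map: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the JSON-ready summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, Any] = {
        "tool": "ovolkit",
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
    }

    def complete(stage: str) -> None:
        manifest.append(stage)
        (outdir / "MANIFEST").write_text(
            "\n".join(f"{s}\tcomplete" for s in manifest) + "\n"
        )

    def guard(stage: str):
        class _Guard:
            def __enter__(self):
                log.info("stage %s", stage)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(stage, exc) from exc
                complete(stage)

        return _Guard()

    records: list[ProteinRecord]
    alignment: AlignmentBlock | None = None
    disorder_annotations: list[RegionAnnotation] = []

    with guard("load"):
        if config.simulate:
            sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
            fam = simulate_family(sim_cfg)
            fam.write(outdir / "simulated")
            records, alignment = fam.records, fam.alignment
            tracks = emit_disorder_tracks(fam, seed=config.seed)
            disorder_annotations = [
                ann
                for tr in tracks.values()
                for ann in call_disordered_regions(tr, config.min_disorder_len)
            ]
        elif config.fasta:
            records = read_fasta(config.fasta)
            if config.alignment:
                alignment = read_alignment(config.alignment)
        else:
            raise ValueError("config needs either 'fasta' or 'simulate: true'")
        summary["n_sequences"] = len(records)

    pat = parse_pattern(config.pattern)

    with guard("scan"):
        all_matches = [m for rec in records for m in scan(rec, pat)]
        write_tsv(matches_to_frame(all_matches), outdir / "motif_matches.tsv")
        summary["n_motif_matches"] = len(all_matches)

    with guard("architecture"):
        archs, failures = [], []
        for rec in records:
            try:
                archs.append(
                    build_architecture(rec, pat, disorder_annotations, max_linker=config.max_linker)
                )
            except TetradNotFoundError as err:
                failures.append({"seq_id": rec.id, "n_matches": len(err.matches)})
        if archs:
            table = summarize_architectures(archs)
            write_tsv(table, outdir / "architectures.tsv")
            summary["architectures"] = {
                "n": len(archs),
                "length_range": list(table.attrs["length_range"]),
                "sides": table["extension_side"].value_counts().to_dict(),
            }
        summary["tetrad_failures"] = failures

    with guard("bias"):
        patches = [
            p
            for rec in records
            for p in find_bias_patches(rec, config.bias_window, config.bias_min_frac)
        ]
        write_annotations(patches, outdir / "bias_patches.tsv")
        summary["n_bias_patches"] = len(patches)

    with guard("disorder"):
        for path in config.disorder_tables:
            track = parse_disorder_table(path)
            disorder_annotations.extend(
                call_disordered_regions(track, config.min_disorder_len)
            )
        write_annotations(disorder_annotations, outdir / "disordered_regions.tsv")
        summary["n_disordered_regions"] = len(disorder_annotations)

    if alignment is not None and alignment.n_rows >= 3:
        with guard("divergence"):
            pset, kw, box = compare_partitions(
                alignment, disorder_annotations, config.rule_frac, seed=config.seed
            )
            write_tsv(box, outdir / "partition_boxplot.tsv")
            dm = distance_matrix(alignment)
            dm.to_frame().to_csv(outdir / "distance_matrix.tsv", sep="\t")
            (outdir / "distances.phylip").write_text(dm.to_phylip_lower())
            summary["divergence"] = {
                "overall_mean_distance": dm.overall_mean(),
                "partition_medians": {
                    row["partition"]: row["median"] for _, row in box.iterrows()
                },
                "kruskal_wallis": None
                if kw is None
                else {"H": kw.H, "df": kw.df, "p_value": kw.p_value,
                      "tie_correction": kw.tie_correction,
                      "group_sizes": kw.group_sizes},
            }
        with guard("nj"):
            if not dm.has_undefined() and dm.n >= 3:
                newick = nj_tree(dm)
                (outdir / "nj_tree.nwk").write_text(newick + "\n")
                summary["nj_tree"] = newick

    if config.loci_table:
        with guard("synteny"):
            cards = read_locus_table(config.loci_table)
            fam_map = read_family_map(config.family_map) if config.family_map else None
            labels = sorted(cards)
            calls = [
                classify_locus_pair(cards[a], cards[b], fam_map)
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
                if cards[a].focal_gene and cards[b].focal_gene
            ]
            write_tsv(calls_to_frame(calls), outdir / "synteny_calls.tsv")
            summary["synteny_verdicts"] = calls_to_frame(calls)["verdict"].value_counts().to_dict() if calls else {}

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    complete("summary")
    return summary
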