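"""Per-residue disorder tracks and compositional-bias ("X-rich") patches.

Disorder prediction itself (a trained SVM in tools like DISOPRED2) is not
re-implemented here; this module consumes the per-residue output table such
tools emit — position, residue, score in [0, 1], optional ordered/disordered
state — and turns it into interval annotations.  Compositional bias is
detected directly from sequence with a sliding window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import Interval, ProteinRecord, read_tsv, write_tsv

__all__ = [
    "DisorderTrack",
    "RegionAnnotation",
    "parse_disorder_table",
    "call_disordered_regions",
    "find_bias_patches",
    "annotations_to_frame",
    "read_annotations",
    "write_annotations",
]

REGION_KINDS = {"disordered", "x-rich", "motif", "core", "n-extension", "c-extension"}


@dataclass(frozen=True)
class RegionAnnotation:
    """A kind-tagged 1-based closed interval on a sequence.

    ``detail`` carries free text; for ``x-rich`` it names the single
    dominant residue (optionally with its in-patch frequency).  Overlapping
    annotations of different kinds are legitimate and preserved — e.g. a
    His-rich patch inside an Asn-rich one.
    """

    sequence_id: str
    iv: Interval
    kind: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass
class DisorderTrack:
    """Per-residue disorder scores/states for one sequence."""

    sequence_id: str
    scores: np.ndarray  # float in [0, 1]
    states: np.ndarray  # bool, True = disordered
    threshold: float = 0.5
    residues: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.states = np.asarray(self.states, dtype=bool)
        if self.scores.shape != self.states.shape:
            raise ValueError("scores and states differ in length")

    def __len__(self) -> int:
        return len(self.scores)


def parse_disorder_table(path: str | Path, threshold: float = 0.5) -> DisorderTrack:
    """Parse a per-residue disorder TSV into a :class:`DisorderTrack`.

    Expected columns: ``position`` (contiguous from 1), ``residue``, and
    ``score`` and/or ``state`` ('*' or 'disordered'/'D' marking disorder).
    A missing state column is derived as ``score >= threshold``.
    """
    df = read_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: empty disorder table")
    cols = {c.lower(): c for c in df.columns}
    if "position" not in cols:
        raise ValueError(f"{path}: no 'position' column")
    pos = df[cols["position"]].astype(int).to_numpy()
    for i, p in enumerate(pos, start=1):
        if p != i:
            raise ValueError(f"{path}: position gap at {i}")
    seq_id = Path(path).stem
    if "seq_id" in cols:
        ids = df[cols["seq_id"]].unique()
        if len(ids) > 1:
            raise ValueError(f"{path}: multiple sequence ids in one table")
        seq_id = str(ids[0])
    residues = "".join(df[cols["residue"]]) if "residue" in cols else ""
    scores = None
    if "score" in cols:
        scores = df[cols["score"]].astype(float).to_numpy()
        if ((scores < 0) | (scores > 1)).any():
            bad = int(np.argmax((scores < 0) | (scores > 1))) + 1
            raise ValueError(f"{path}: score outside [0,1] at position {bad}")
    if "state" in cols:
        raw = df[cols["state"]].str.strip().str.upper()
        states = raw.isin({"*", "D", "DISORDERED", "1", "TRUE"}).to_numpy()
    elif scores is not None:
        states = scores >= threshold
    else:
        raise ValueError(f"{path}: need a 'score' or 'state' column")
    if scores is None:
        scores = np.where(states, 1.0, 0.0)
    return DisorderTrack(seq_id, scores, states, threshold, residues)


def call_disordered_regions(track: DisorderTrack, min_len: int = 5) -> list[RegionAnnotation]:
    """Maximal runs of disordered state of length >= ``min_len``."""
    out: list[RegionAnnotation] = []
    start = None
    states = np.append(track.states, False)  # sentinel closes a trailing run
    for i, d in enumerate(states, start=1):
        if d and start is None:
            start = i
        elif not d and start is not None:
            if i - start >= min_len:
                out.append(RegionAnnotation(track.sequence_id, Interval(start, i - 1), "disordered"))
            start = None
    return out


def find_bias_patches(
    seq: ProteinRecord,
    window: int = 20,
    min_frac: float = 0.35,
) -> list[RegionAnnotation]:
    """Detect single-residue compositional-bias patches (Gln-rich etc.).

    For each residue type, every length-``window`` window in which that
    residue's frequency is >= ``min_frac`` qualifies; overlapping or
    adjacent qualifying windows are merged, and each merged patch is
    trimmed to the first/last occurrence of the biased residue so patch
    boundaries sit on the residue itself.  Patches for different residues
    may overlap; all are reported, each with the dominant residue and its
    frequency within the patch.
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    n = len(seq.residues)
    if n < window:
        warnings.warn(
            f"sequence {seq.id!r} shorter than window ({n} < {window}); no patches"
        )
        return []
    need = min_frac * window
    out: list[RegionAnnotation] = []
    arr = np.frombuffer(seq.residues.encode(), dtype="S1")
    for residue in sorted(set(seq.residues) - {"X"}):
        hits = (arr == residue.encode()).astype(int)
        counts = np.convolve(hits, np.ones(window, dtype=int), mode="valid")
        qualifying = np.nonzero(counts >= need - 1e-9)[0]  # 0-based window starts
        if qualifying.size == 0:
            continue
        # merge overlapping/adjacent qualifying windows into maximal spans
        spans: list[list[int]] = []
        for q in qualifying:
            s, e = q + 1, q + window  # 1-based closed
            if spans and s <= spans[-1][1] + 1:
                spans[-1][1] = max(spans[-1][1], e)
            else:
                spans.append([s, e])
        positions = np.nonzero(hits)[0] + 1
        for s, e in spans:
            inside = positions[(positions >= s) & (positions <= e)]
            if inside.size == 0:
                continue
            iv = Interval(int(inside[0]), int(inside[-1]))
            frac = inside.size / len(iv)
            out.append(
                RegionAnnotation(seq.id, iv, "x-rich", f"{residue}:{frac:.3f}")
            )
    out.sort(key=lambda a: (a.iv.start, a.iv.end, a.detail))
    return out


# ---------------------------------------------------------------------------
# annotation I/O (BED-like TSV, 1-based closed — stated in the file header)
# ---------------------------------------------------------------------------

def annotations_to_frame(annotations: Iterable[RegionAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": a.sequence_id,
                "start": a.iv.start,
                "end": a.iv.end,
                "kind": a.kind,
                "detail": a.detail,
            }
            for a in annotations
        ],
        columns=["seq_id", "start", "end", "kind", "detail"],
    )


def write_annotations(annotations: Iterable[RegionAnnotation], path: str | Path) -> None:
    write_tsv(
        annotations_to_frame(annotations),
        path,
        header_comment="coordinates are 1-based, fully closed",
    )


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    df = read_tsv(path)
    return [
        RegionAnnotation(
            r["seq_id"], Interval(int(r["start"]), int(r["end"])), r["kind"], r.get("detail", "")
        )
        for _, r in df.iterrows()
    ]
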