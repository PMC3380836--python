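"""Pairwise p-distance machinery and partitioned divergence comparison.

The p-distance between two aligned protein sequences is the proportion of
differing sites among *comparable* sites.  Comparability follows pairwise
deletion: a site counts only when both members carry a standard residue —
gaps and the unknown residue ``X`` are excluded per pair, not per column.
Distances are computed on three site sets — all columns (full-length),
structured-only, and disordered-only — and the three resulting distance
collections are compared with the Kruskal-Wallis rank test.  A caveat the
user should know: pairwise distances are not independent observations
(each sequence enters many pairs), so the Kruskal-Wallis p-value is a
descriptive screen, not a calibrated test; the statistic is nevertheless
computed exactly as defined.

A neighbor-joining tree built from the p-distance matrix provides a quick
check that sequences cluster by lineage; it is deliberately lightweight
(no substitution model, no Bayesian inference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .core_io import GAP, STANDARD_AA, AlignmentBlock, project_interval_to_columns
from .disorder import RegionAnnotation

__all__ = [
    "DistanceMatrix",
    "PartitionedDistanceSet",
    "KWResult",
    "p_distance",
    "distance_matrix",
    "bootstrap_variance",
    "partition_columns",
    "kruskal_wallis",
    "compare_partitions",
    "nj_tree",
]


def _comparable_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    std = np.array(sorted(STANDARD_AA), dtype="S1")
    return np.isin(a, std) & np.isin(b, std)


def _as_bytes(row: str) -> np.ndarray:
    return np.frombuffer(row.encode(), dtype="S1")


def p_distance(
    row_a: str,
    row_b: str,
    columns: Sequence[int] | None = None,
) -> tuple[float, int]:
    """p-distance with pairwise deletion on an optional 1-based column subset.

    Returns ``(distance, comparable_sites)``; the distance is ``nan`` when
    no site is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"row length mismatch ({len(row_a)} vs {len(row_b)})")
    a, b = _as_bytes(row_a.upper()), _as_bytes(row_b.upper())
    if columns is not None:
        idx = np.asarray(columns, dtype=int) - 1
        if idx.size and (idx.min() < 0 or idx.max() >= len(a)):
            raise ValueError("column subset out of bounds")
        a, b = a[idx], b[idx]
    mask = _comparable_mask(a, b)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    diff = int((a[mask] != b[mask]).sum())
    return diff / n, n


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    taxa: list[str]
    values: np.ndarray          # (n, n) float, nan where undefined
    site_counts: np.ndarray     # (n, n) int
    bootstrap_variances: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.taxa)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def overall_mean(self) -> float:
        """Mean of the defined off-diagonal entries."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (defined pairs only)."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        return vals[np.isfinite(vals)]

    def has_undefined(self) -> bool:
        iu = np.triu_indices(self.n, k=1)
        return bool(np.isnan(self.values[iu]).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_phylip_lower(self) -> str:
        lines = [str(self.n)]
        for i, t in enumerate(self.taxa):
            vals = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
            lines.append(f"{t:<12s}{vals}".rstrip())
        return "\n".join(lines) + "\n"


def distance_matrix(block: AlignmentBlock, columns: Sequence[int] | None = None) -> DistanceMatrix:
    """All-pairs p-distances (pairwise deletion) for an alignment."""
    if block.n_rows < 2:
        raise ValueError("need at least two rows")
    n = block.n_rows
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = sum(1 for ch in block.rows[i] if ch != GAP)
        for j in range(i + 1, n):
            d, c = p_distance(block.rows[i], block.rows[j], columns)
            values[i, j] = values[j, i] = d
            counts[i, j] = counts[j, i] = c
    return DistanceMatrix(list(block.ids), values, counts)


def bootstrap_variance(
    block: AlignmentBlock,
    pair: tuple[str, str],
    replicates: int = 1000,
    seed: int | None = None,
    columns: Sequence[int] | None = None,
) -> tuple[float, int]:
    """Bootstrap variance of one pair's p-distance by column resampling.

    Columns (of the subset, when given) are resampled with replacement per
    replicate and the p-distance recomputed; replicates in which the pair
    has no comparable site are excluded.  Returns the unbiased sample
    variance over the retained replicates and the retained count.
    Deterministic for a fixed seed.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    a, b = (block.row(pair[0]), block.row(pair[1]))
    pool = np.asarray(columns, dtype=int) if columns is not None else np.arange(1, block.n_cols + 1)
    dists = []
    for _ in range(replicates):
        resampled = rng.choice(pool, size=pool.size, replace=True)
        d, c = p_distance(a, b, resampled)
        if c > 0:
            dists.append(d)
    if len(dists) < 2:
        return float("nan"), len(dists)
    return float(np.var(dists, ddof=1)), len(dists)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def partition_columns(
    block: AlignmentBlock,
    annotations: Iterable[RegionAnnotation],
    rule_frac: float = 0.5,
) -> tuple[list[int], list[int]]:
    """Split alignment columns into (structured, disordered) sets.

    Disorder calls are per sequence; each row's ``kind='disordered'``
    annotations are projected onto alignment columns, and a column is
    classed disordered when more than ``rule_frac`` of its non-gap
    residues are disorder-annotated in their own row.  All-gap columns
    fall to the structured set.
    """
    anns = [a for a in annotations if a.kind == "disordered"]
    known = set(block.ids)
    for a in anns:
        if a.sequence_id not in known:
            raise ValueError(f"annotation references unknown row {a.sequence_id!r}")
    ncol = block.n_cols
    dis_counts = np.zeros(ncol, dtype=int)
    nongap_counts = np.zeros(ncol, dtype=int)
    per_row_flags = {rid: np.zeros(ncol, dtype=bool) for rid in block.ids}
    for a in anns:
        row = block.row(a.sequence_id)
        cols = project_interval_to_columns(row, a.iv)
        flags = per_row_flags[a.sequence_id]
        for c in range(cols.start, cols.end + 1):
            if row[c - 1] != GAP:
                flags[c - 1] = True
    for rid, row in block:
        for c, ch in enumerate(row):
            if ch != GAP:
                nongap_counts[c] += 1
                if per_row_flags[rid][c]:
                    dis_counts[c] += 1
    disordered, structured = [], []
    for c in range(ncol):
        if nongap_counts[c] > 0 and dis_counts[c] > rule_frac * nongap_counts[c]:
            disordered.append(c + 1)
        else:
            structured.append(c + 1)
    return structured, disordered


@dataclass
class PartitionedDistanceSet:
    """Distance collections on full-length / structured / disordered sites."""

    full: np.ndarray
    structured: np.ndarray
    disordered: np.ndarray
    structured_columns: list[int] = field(default_factory=list)
    disordered_columns: list[int] = field(default_factory=list)
    empty_partitions: list[str] = field(default_factory=list)

    def groups(self) -> dict[str, np.ndarray]:
        d = {"full": self.full, "structured": self.structured, "disordered": self.disordered}
        return {k: v for k, v in d.items() if k not in self.empty_partitions and v.size}


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

@dataclass
class KWResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value."""

    H: float
    df: int
    tie_correction: float
    p_value: float
    group_sizes: list[int]
    permutation_p: float | None = None


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    *,
    permutation: int = 0,
    seed: int | None = None,
) -> KWResult:
    """Kruskal-Wallis rank test across k labelled value collections.

    Midranks are assigned over the pooled values; the raw statistic
    ``H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2`` is divided by the
    tie correction ``1 - sum(t^3 - t)/(N^3 - N)``; ``H = 0`` by convention
    when every pooled value is identical.  The p-value uses the chi-square
    approximation with k-1 df; ``permutation > 0`` adds a seeded
    permutation p-value for small samples.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    sizes = [int(g.size) for g in arrays]
    k = len(arrays)
    pooled = np.concatenate(arrays)
    N = pooled.size
    if N < 3:
        raise ValueError("need at least 3 values in total")

    def _H(pool: np.ndarray, sz: list[int]) -> tuple[float, float]:
        ranks = sps.rankdata(pool)
        raw = 0.0
        offset = 0
        for n_i in sz:
            rbar = ranks[offset : offset + n_i].mean()
            raw += n_i * (rbar - (N + 1) / 2.0) ** 2
            offset += n_i
        raw *= 12.0 / (N * (N + 1))
        _, t_counts = np.unique(pool, return_counts=True)
        tie = 1.0 - float(((t_counts**3 - t_counts).sum()) / (N**3 - N))
        if tie == 0.0:  # all values identical
            return 0.0, 0.0
        return raw / tie, tie

    H, tie = _H(pooled, sizes)
    df = k - 1
    p = float(sps.chi2.sf(H, df))
    perm_p = None
    if permutation > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            h_perm, _ = _H(perm, sizes)
            if h_perm >= H - 1e-12:
                count += 1
        perm_p = (count + 1) / (permutation + 1)
    return KWResult(float(H), df, tie, p, sizes, perm_p)


# ---------------------------------------------------------------------------
# the partition comparison (the box-plot analysis)
# ---------------------------------------------------------------------------

def five_number_summary(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
    }


def compare_partitions(
    block: AlignmentBlock,
    annotations: Iterable[RegionAnnotation],
    rule_frac: float = 0.5,
    seed: int | None = None,
    *,
    permutation: int = 0,
    pair_rule: Literal["column", "pairwise"] = "column",
) -> tuple[PartitionedDistanceSet, KWResult | None, pd.DataFrame]:
    """Compare divergence of structured vs disordered vs full-length sites.

    Pairwise p-distances are computed on the full column set and on the
    structured-only and disordered-only subsets; the three distance
    collections are compared by Kruskal-Wallis and summarized as
    box-plot five-number rows.  ``pair_rule='column'`` partitions by
    column majority vote (default); ``'pairwise'`` classes each site per
    sequence pair — a site is disordered for a pair only when both
    members' residues are disorder-annotated — for users who prefer
    per-sequence segments over alignment columns.

    Returns ``(PartitionedDistanceSet, KWResult | None, summary frame)``;
    the KW result is ``None`` when fewer than two partitions are non-empty.
    """
    if block.n_rows < 3:
        raise ValueError("need at least 3 rows")
    annotations = list(annotations)
    structured_cols, disordered_cols = partition_columns(block, annotations, rule_frac)
    full = distance_matrix(block).condensed()
    if pair_rule == "column":
        structured = (
            distance_matrix(block, structured_cols).condensed()
            if structured_cols else np.array([])
        )
        disordered = (
            distance_matrix(block, disordered_cols).condensed()
            if disordered_cols else np.array([])
        )
    else:
        structured, disordered = _pairwise_rule_distances(block, annotations)
    pset = PartitionedDistanceSet(
        full, structured, disordered, structured_cols, disordered_cols
    )
    for name, cols in (("structured", structured_cols), ("disordered", disordered_cols)):
        arr = getattr(pset, name)
        if (pair_rule == "column" and not cols) or arr.size == 0:
            pset.empty_partitions.append(name)
    groups = pset.groups()
    kw = (
        kruskal_wallis(list(groups.values()), permutation=permutation, seed=seed)
        if len(groups) >= 2 else None
    )
    rows = []
    for name in ("structured", "disordered", "full"):
        arr = getattr(pset, name)
        row = {"partition": name, **five_number_summary(arr), "n_pairs": int(arr.size)}
        rows.append(row)
    return pset, kw, pd.DataFrame(rows)


def _pairwise_rule_distances(
    block: AlignmentBlock, annotations: Iterable[RegionAnnotation]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair site classing: disordered when both members are annotated."""
    ncol = block.n_cols
    flags = {rid: np.zeros(ncol, dtype=bool) for rid in block.ids}
    for a in annotations:
        if a.kind != "disordered":
            continue
        row = block.row(a.sequence_id)
        cols = project_interval_to_columns(row, a.iv)
        for c in range(cols.start, cols.end + 1):
            if row[c - 1] != GAP:
                flags[a.sequence_id][c - 1] = True
    std = np.array(sorted(STANDARD_AA), dtype="S1")
    structured, disordered = [], []
    ids = block.ids
    for i in range(len(ids)):
        ai = _as_bytes(block.rows[i])
        for j in range(i + 1, len(ids)):
            bj = _as_bytes(block.rows[j])
            comparable = np.isin(ai, std) & np.isin(bj, std)
            both_dis = flags[ids[i]] & flags[ids[j]]
            for target, mask in (
                (disordered, comparable & both_dis),
                (structured, comparable & ~both_dis),
            ):
                n = int(mask.sum())
                if n:
                    target.append(float((ai[mask] != bj[mask]).sum() / n))
    return np.asarray(structured), np.asarray(disordered)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree (Newick, branch lengths) from a
    fully-defined distance matrix.  Negative branch lengths are clamped to
    zero.  NJ reconstructs additive matrices exactly, which makes it a
    cheap clustering check on p-distance matrices."""
    if matrix.n < 3:
        raise ValueError("need at least 3 taxa")
    if matrix.has_undefined():
        raise ValueError("distance matrix has undefined entries")
    dm = _SkbioDM(matrix.values, ids=matrix.taxa)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()
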