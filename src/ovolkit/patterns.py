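"""Prosite-dialect motif patterns: parsing, scanning, tetrad detection,
consensus-pattern derivation, and sequence-logo matrices.

The dialect is the subset used to describe C2H2 zinc fingers:

* a bare residue letter (``C``),
* a bracket set (``[FWsgat]``) whose lowercase members are *exceptional*
  residues — rarely observed members, rendered lowercase but matched
  identically to uppercase (major) members,
* wildcards ``x``, ``x(n)``, ``x(n,m)``,
* elements joined by ``-``.

Prosite's ``{...}`` exclusion sets and the ``<``/``>`` anchors are outside
the dialect and rejected with a clear message.

Scanning convention: an unknown residue ``X`` in a sequence matches
wildcards only — it cannot certify membership of a bracket set or a fixed
letter.  Variable-width wildcards are expanded shortest-first at each
anchor; the default ``leftmost-non-overlapping`` mode produces the greedy
left-to-right cover used for motif counting (zinc fingers do not overlap).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core_io import GAP, STANDARD_AA, AlignmentBlock, Interval, ProteinRecord

__all__ = [
    "PatternElement",
    "PatternSpec",
    "MotifMatch",
    "LogoMatrix",
    "PatternSyntaxError",
    "parse_pattern",
    "render_pattern",
    "scan",
    "find_tetrad",
    "rightmost_tetrad",
    "derive_pattern",
    "logo_matrix",
    "PS00028",
    "OVOL_MOTIF_PATTERNS",
    "OVOL_OVERALL_PATTERN",
]

#: Generic C2H2 zinc-finger pattern (Prosite accession PS00028).
PS00028 = "C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H"
#: Per-motif C2H2 consensus patterns for the OVOL tetrad (motifs I-IV).
OVOL_MOTIF_PATTERNS = {
    "I": "C-x(2)-C-x(3)-[FW]-x(8)-H-x(3)-H",
    "II": "C-x(2)-C-x(3)-[F]-x(8)-H-x(3)-H",
    "III": "C-x(2)-C-x(3)-[F]-x(8)-H-x(4)-H",
    "IV": "C-x(2)-C-x(3)-[Fsgat]-x(8)-H-x(4)-H",
}
#: Overall OVOL C2H2 consensus (lowercase = exceptional residues).
OVOL_OVERALL_PATTERN = "C-x(2)-C-x(3)-[FWsgat]-x(8)-H-x(3,4)-H"

LOG2_20 = math.log2(20)


class PatternSyntaxError(ValueError):
    """Malformed pattern text; carries the offending offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: a fixed residue set or a bounded wildcard."""

    kind: Literal["fixed-set", "wildcard"]
    major: frozenset[str] = frozenset()
    exceptional: frozenset[str] = frozenset()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind == "fixed-set":
            if not (self.major | self.exceptional):
                raise ValueError("fixed-set element with no residues")
            if self.min_repeat != 1 or self.max_repeat != 1:
                raise ValueError("fixed-set elements are single-position")
        else:
            if not (0 <= self.min_repeat <= self.max_repeat):
                raise ValueError(
                    f"bad wildcard bounds ({self.min_repeat}, {self.max_repeat})"
                )

    @property
    def allowed(self) -> frozenset[str]:
        return self.major | self.exceptional

    def matches_residue(self, ch: str) -> bool:
        """Whether one sequence character satisfies this element once."""
        if self.kind == "wildcard":
            return ch != GAP
        return ch in self.allowed  # 'X' is never a set member


@dataclass(frozen=True)
class PatternSpec:
    """A parsed pattern: ordered elements plus the source text."""

    elements: tuple[PatternElement, ...]
    source_text: str

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """A pattern occurrence on a sequence (1-based closed interval)."""

    sequence_id: str
    iv: Interval
    pattern_label: str
    matched_text: str

    def __post_init__(self) -> None:
        if len(self.matched_text) != len(self.iv):
            raise ValueError("matched text length disagrees with interval")


# ---------------------------------------------------------------------------
# parsing / rendering
# ---------------------------------------------------------------------------

_COUNT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)")


def parse_pattern(text: str) -> PatternSpec:
    """Parse a Prosite-dialect pattern string into a :class:`PatternSpec`."""
    elements: list[PatternElement] = []
    i, n = 0, len(text)
    if not text.strip():
        raise PatternSyntaxError("empty pattern", 0)
    expecting_element = True
    while i < n:
        ch = text[i]
        if ch == "-":
            if expecting_element:
                raise PatternSyntaxError("unexpected separator", i)
            expecting_element = True
            i += 1
            continue
        if not expecting_element:
            raise PatternSyntaxError("missing '-' separator", i)
        if ch in "{<>":
            raise PatternSyntaxError(
                f"{ch!r} is outside the supported dialect "
                "(exclusion sets and anchors are not used)", i
            )
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternSyntaxError("unterminated '['", i)
            body = text[i + 1 : j]
            if not body:
                raise PatternSyntaxError("empty residue set", i)
            major, exceptional = set(), set()
            for k, c in enumerate(body):
                if c.isupper() and c in STANDARD_AA:
                    major.add(c)
                elif c.islower() and c.upper() in STANDARD_AA:
                    exceptional.add(c.upper())
                else:
                    raise PatternSyntaxError(f"invalid set member {c!r}", i + 1 + k)
            elements.append(
                PatternElement("fixed-set", frozenset(major), frozenset(exceptional))
            )
            i = j + 1
        elif ch in ("x", "X"):
            i += 1
            lo = hi = 1
            if i < n and text[i] == "(":
                m = _COUNT_RE.match(text, i)
                if not m:
                    raise PatternSyntaxError("malformed repeat count", i)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if hi < lo:
                    raise PatternSyntaxError("repeat max below min", i)
                i = m.end()
            elements.append(PatternElement("wildcard", min_repeat=lo, max_repeat=hi))
        elif ch.upper() in STANDARD_AA:
            major = {ch} if ch.isupper() else set()
            exc = {ch.upper()} if ch.islower() else set()
            elements.append(
                PatternElement("fixed-set", frozenset(major), frozenset(exc))
            )
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r}", i)
        expecting_element = False
    if expecting_element:
        raise PatternSyntaxError("trailing separator", n - 1)
    return PatternSpec(tuple(elements), text)


def render_pattern(
    spec: PatternSpec,
    *,
    residue_order: dict[int, Sequence[str]] | None = None,
) -> str:
    """Render a :class:`PatternSpec` back to dialect text.

    Majors are rendered uppercase before lowercase exceptionals.  Within
    each class residues are alphabetical unless ``residue_order`` supplies
    an explicit ordering for an element index (used by
    :func:`derive_pattern` to preserve observed-frequency order).
    """
    parts: list[str] = []
    for idx, e in enumerate(spec.elements):
        if e.kind == "wildcard":
            if e.min_repeat == e.max_repeat == 1:
                parts.append("x")
            elif e.min_repeat == e.max_repeat:
                parts.append(f"x({e.min_repeat})")
            else:
                parts.append(f"x({e.min_repeat},{e.max_repeat})")
            continue
        order = list(residue_order.get(idx, [])) if residue_order else []

        def _sorted(members: frozenset[str]) -> list[str]:
            in_order = [r for r in order if r in members]
            rest = sorted(members - set(in_order))
            return in_order + rest

        majors = _sorted(e.major)
        excs = [r.lower() for r in _sorted(e.exceptional)]
        if len(majors) == 1 and not excs:
            parts.append(majors[0])
        else:
            parts.append("[" + "".join(majors + excs) + "]")
    return "-".join(parts)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _match_lengths_from(seq: str, start0: int, elements: tuple[PatternElement, ...]) -> list[int]:
    """All match lengths anchored at 0-based ``start0``, shortest first."""
    out: list[int] = []

    def walk(pos: int, elem_idx: int) -> None:
        if elem_idx == len(elements):
            out.append(pos - start0)
            return
        e = elements[elem_idx]
        if e.kind == "fixed-set":
            if pos < len(seq) and e.matches_residue(seq[pos]):
                walk(pos + 1, elem_idx + 1)
            return
        # wildcard: shortest-first expansion
        for take in range(e.min_repeat, e.max_repeat + 1):
            if pos + take > len(seq):
                break
            walk(pos + take, elem_idx + 1)

    walk(start0, 0)
    return sorted(set(out))


def scan(
    seq: ProteinRecord,
    pat: PatternSpec,
    mode: Literal["leftmost-non-overlapping", "all-overlapping"] = "leftmost-non-overlapping",
    *,
    label: str | None = None,
) -> list[MotifMatch]:
    """Find pattern occurrences in a sequence.

    ``all-overlapping`` returns every (start, length) satisfying the
    pattern.  ``leftmost-non-overlapping`` walks left to right, takes the
    shortest match at each matching anchor, and resumes after its end —
    the greedy cover appropriate for counting tandem zinc fingers.
    """
    label = label or pat.source_text
    residues = seq.residues
    matches: list[MotifMatch] = []
    if mode == "all-overlapping":
        for s0 in range(len(residues)):
            for length in _match_lengths_from(residues, s0, pat.elements):
                if length == 0:
                    continue
                iv = Interval(s0 + 1, s0 + length)
                matches.append(MotifMatch(seq.id, iv, label, residues[s0 : s0 + length]))
        return matches
    s0 = 0
    while s0 < len(residues):
        lengths = [ln for ln in _match_lengths_from(residues, s0, pat.elements) if ln > 0]
        if lengths:
            length = lengths[0]
            iv = Interval(s0 + 1, s0 + length)
            matches.append(MotifMatch(seq.id, iv, label, residues[s0 : s0 + length]))
            s0 += length
        else:
            s0 += 1
    return matches


def find_tetrad(
    matches: Sequence[MotifMatch],
    max_linker: int = 20,
    *,
    prefer: Literal["first", "last"] = "first",
) -> tuple[MotifMatch, MotifMatch, MotifMatch, MotifMatch] | None:
    """Find four consecutive non-overlapping motifs with short linkers.

    A valid tetrad is a window of four matches, each starting after the
    previous ends, with every inter-motif gap at most ``max_linker``
    residues.  ``prefer='first'`` returns the leftmost such window;
    ``prefer='last'`` the rightmost (used to pick the C-terminal tetrad of
    proteins carrying extra upstream fingers).
    """
    ms = sorted(matches, key=lambda m: (m.iv.start, m.iv.end))
    windows: list[tuple[MotifMatch, ...]] = []
    for i in range(len(ms) - 3):
        window = ms[i : i + 4]
        ok = True
        for a, b in zip(window, window[1:]):
            gap = b.iv.start - a.iv.end - 1
            if gap < 0 or gap > max_linker:
                ok = False
                break
        if ok:
            windows.append(tuple(window))
    if not windows:
        return None
    chosen = windows[0] if prefer == "first" else windows[-1]
    return chosen  # type: ignore[return-value]


def rightmost_tetrad(
    matches: Sequence[MotifMatch],
    max_linker: int = 20,
) -> tuple[MotifMatch, MotifMatch, MotifMatch, MotifMatch] | None:
    """The C-terminal-most compact tetrad among (possibly overlapping)
    matches.

    Motif IV is chosen as the rightmost match, then each preceding motif
    as the rightmost match that leaves a linker of 0..``max_linker``
    residues, backtracking when a choice strands the chain.  Robust to
    spurious overlapping matches (e.g. a chance cysteine just upstream of
    a real finger), which the greedy left-to-right cover is not.
    """
    ms = sorted(matches, key=lambda m: (-m.iv.end, -m.iv.start))
    chain: list[MotifMatch] = []

    def search(remaining: int, next_start: int | None) -> bool:
        for m in ms:
            if next_start is not None:
                gap = next_start - m.iv.end - 1
                if gap < 0 or gap > max_linker:
                    continue
            chain.append(m)
            if remaining == 1 or search(remaining - 1, m.iv.start):
                return True
            chain.pop()
        return False

    if not search(4, None):
        return None
    return tuple(reversed(chain))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# consensus-pattern derivation
# ---------------------------------------------------------------------------

def derive_pattern(
    instances: AlignmentBlock,
    f_major: float = 0.2,
    f_wild: float = 0.5,
) -> str:
    """Derive a consensus pattern from aligned motif instances.

    Per column (frequencies over non-gap residues): residues at frequency
    >= ``f_major`` become major (uppercase) members; residues observed
    below ``f_major`` become exceptional (lowercase) members; when the top
    residue frequency is below ``f_wild`` the column is a wildcard.
    Consecutive wildcard columns consolidate to ``x(n)``, or ``x(n,m)``
    when instance gap patterns make the covered lengths vary.  Members are
    rendered by descending frequency, ties by first appearance down the
    column, reproducing observed-order brackets such as ``[FWsgat]``.
    """
    if instances.n_rows < 2:
        raise ValueError("need at least two aligned instances")
    if f_major <= 0:
        raise ValueError("f_major must be positive")
    n_cols = instances.n_cols

    col_kind: list[str] = []  # 'fixed' or 'wild'
    col_elements: list[PatternElement | None] = []
    col_order: list[list[str]] = []
    for c in range(1, n_cols + 1):
        col = instances.column(c)
        residues = [ch for ch in col if ch != GAP]
        if len(residues) < instances.n_rows:
            # some instance lacks this column: it joins a wildcard run so
            # the derived pattern still matches every instance
            col_kind.append("wild")
            col_elements.append(None)
            col_order.append([])
            continue
        counts: dict[str, int] = {}
        first_seen: dict[str, int] = {}
        for i, ch in enumerate(residues):
            counts[ch] = counts.get(ch, 0) + 1
            first_seen.setdefault(ch, i)
        total = len(residues)
        top = max(counts.values()) / total
        if top < f_wild:
            col_kind.append("wild")
            col_elements.append(None)
            col_order.append([])
            continue
        major = frozenset(r for r, k in counts.items() if k / total >= f_major)
        exc = frozenset(r for r in counts if r not in major)
        order = sorted(counts, key=lambda r: (-counts[r], first_seen[r]))
        col_kind.append("fixed")
        col_elements.append(PatternElement("fixed-set", major, exc))
        col_order.append(order)

    # consolidate wildcard runs, measuring per-instance covered lengths
    elements: list[PatternElement] = []
    orders: dict[int, Sequence[str]] = {}
    c = 0
    while c < n_cols:
        if col_kind[c] == "fixed":
            orders[len(elements)] = col_order[c]
            elements.append(col_elements[c])  # type: ignore[arg-type]
            c += 1
            continue
        run_start = c
        while c < n_cols and col_kind[c] == "wild":
            c += 1
        covered = [
            sum(1 for cc in range(run_start, c) if row[cc] != GAP)
            for row in instances.rows
        ]
        elements.append(
            PatternElement("wildcard", min_repeat=min(covered), max_repeat=max(covered))
        )
    spec = PatternSpec(tuple(elements), "")
    return render_pattern(spec, residue_order=orders)


# ---------------------------------------------------------------------------
# logo matrices
# ---------------------------------------------------------------------------

AA_ORDER = sorted(STANDARD_AA)


@dataclass
class LogoMatrix:
    """Per-column residue frequencies and information content (bits).

    Frequencies are renormalized over non-gap residues; information is
    ``log2(20) - H`` with the optional small-sample correction
    ``e_n = 19 / (2 ln2 n)`` subtracted (n = non-gap count), clamped at 0.
    All-gap columns carry zero frequencies, zero information, and are
    listed in ``all_gap_columns``.
    """

    frequencies: pd.DataFrame  # columns = AA_ORDER, index = 1-based column
    information: np.ndarray
    n_instances: int
    non_gap_counts: np.ndarray
    all_gap_columns: list[int] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return len(self.information)

    def to_frame(self) -> pd.DataFrame:
        df = self.frequencies.copy()
        df.insert(0, "column", df.index)
        df["information_bits"] = self.information
        return df.reset_index(drop=True)


def logo_matrix(instances: AlignmentBlock, small_sample_correction: bool = True) -> LogoMatrix:
    """Compute the sequence-logo frequency/information matrix of aligned
    motif instances (the data behind a WebLogo-style figure)."""
    n_cols = instances.n_cols
    freq = np.zeros((n_cols, len(AA_ORDER)))
    info = np.zeros(n_cols)
    non_gap = np.zeros(n_cols, dtype=int)
    all_gap: list[int] = []
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    for c in range(1, n_cols + 1):
        col = [ch for ch in instances.column(c) if ch != GAP]
        non_gap[c - 1] = len(col)
        if not col:
            all_gap.append(c)
            continue
        for ch in col:
            if ch in aa_index:
                freq[c - 1, aa_index[ch]] += 1
        total = freq[c - 1].sum()
        if total == 0:  # column of only X residues
            all_gap.append(c)
            continue
        freq[c - 1] /= total
        p = freq[c - 1][freq[c - 1] > 0]
        entropy = float(-(p * np.log2(p)).sum())
        bits = LOG2_20 - entropy
        if small_sample_correction:
            bits -= 19.0 / (2.0 * math.log(2) * len(col))
        info[c - 1] = max(bits, 0.0)
    frame = pd.DataFrame(freq, columns=AA_ORDER, index=range(1, n_cols + 1))
    return LogoMatrix(frame, info, instances.n_rows, non_gap, all_gap)


def matches_to_frame(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """Tabulate matches as (seq_id, start, end, pattern_label, matched_text)."""
    return pd.DataFrame(
        [
            {
                "seq_id": m.sequence_id,
                "start": m.iv.start,
                "end": m.iv.end,
                "pattern_label": m.pattern_label,
                "matched_text": m.matched_text,
            }
            for m in matches
        ],
        columns=["seq_id", "start", "end", "pattern_label", "matched_text"],
    )
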