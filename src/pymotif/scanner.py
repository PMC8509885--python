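"""PY-motif scanning core.

WW domains of Nedd4-family ubiquitin ligases recognise short linear PY
motifs — PPxY or LPxY, where x is any residue — in interactor sequences.
This module compiles such patterns, enumerates every occurrence in a
protein (including overlapping and nested ones), extracts flanked context
slices for consensus building, classifies proteins by motif content,
summarises prevalence over a whole interactome, applies the P<->L
first-residue flip control and benchmarks detections against a labelled
reference set.

Coordinates are 0-based half-open internally; written reports use 1-based
inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import ALPHABET, STANDARD_RESIDUES, ProteinRecord

WILDCARD = None

# regex class covering the full stored alphabet; sequences are validated on
# construction so '.' would do, but the explicit class keeps intent visible
_ANY = "[" + "".join(sorted(ALPHABET)) + "]"


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif: fixed residues and wildcard slots, left to right.

    ``positions`` holds the fixed residue character, or ``None`` for a
    wildcard. Fixed positions match only their exact residue (never the
    ambiguity codes); a wildcard matches any alphabet symbol.
    """

    name: str
    positions: tuple

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"pattern {self.name!r}: length must be >= 3")
        if all(p is WILDCARD for p in self.positions):
            raise ValueError(f"pattern {self.name!r}: needs at least one fixed position")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def wildcard_indices(self) -> tuple:
        return tuple(i for i, p in enumerate(self.positions) if p is WILDCARD)


def compile_pattern(spec: str) -> MotifPattern:
    """Compile a motif spec string like ``"PPxY"`` into a :class:`MotifPattern`.

    Uppercase letters are fixed standard residues; lowercase ``x`` is a
    wildcard. Raises ``ValueError`` on illegal characters, length < 3 or an
    all-wildcard spec.
    """
    positions = []
    for ch in spec:
        if ch == "x":
            positions.append(WILDCARD)
        elif ch in STANDARD_RESIDUES:
            positions.append(ch)
        else:
            raise ValueError(
                f"pattern spec {spec!r}: illegal character {ch!r} "
                "(uppercase standard residues and lowercase 'x' only)"
            )
    return MotifPattern(name=spec, positions=tuple(positions))


#: The canonical built-in patterns.
PPY = compile_pattern("PPY")
PPXY = compile_pattern("PPxY")
LPXY = compile_pattern("LPxY")
BUILTIN_PATTERNS = (PPY, PPXY, LPXY)
#: Default patterns for prevalence / flip / benchmark analyses.
PY_PATTERNS = (PPXY, LPXY)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in one protein.

    ``x_residue`` is the residue at the wildcard slot (absent for patterns
    without exactly one wildcard, e.g. PPY); ``x_minus1_residue`` is the
    residue immediately N-terminal to the motif, absent when the motif
    starts the sequence. ``x_nonstandard`` flags hits whose x residue is an
    ambiguity code.
    """

    protein_id: str
    pattern_name: str
    start: int
    end: int
    matched: str
    x_residue: Optional[str] = None
    x_minus1_residue: Optional[str] = None
    x_nonstandard: bool = False


@dataclass(frozen=True)
class ContextSlice:
    """A motif hit plus up to ``flank`` residues on each side.

    The window is clipped at the sequence termini; ``left_truncated`` and
    ``right_truncated`` count the residues lost to clipping on each side.
    """

    hit: MotifHit
    flank: int
    window: str
    left_truncated: int
    right_truncated: int

    def __post_init__(self) -> None:
        motif_len = self.hit.end - self.hit.start
        expect = (self.flank - self.left_truncated) + motif_len + (
            self.flank - self.right_truncated
        )
        if len(self.window) != expect:
            raise ValueError(
                f"window length {len(self.window)} inconsistent with flank "
                f"{self.flank} and truncations ({self.left_truncated}, "
                f"{self.right_truncated})"
            )


@lru_cache(maxsize=None)
def _compiled_regex(positions: tuple) -> "re.Pattern":
    parts = [_ANY if p is WILDCARD else re.escape(p) for p in positions]
    # lookahead capture so overlapping occurrences are all enumerated
    return re.compile("(?=(" + "".join(parts) + "))")


def scan(record: ProteinRecord, patterns: Iterable[MotifPattern] = PY_PATTERNS) -> list:
    """Enumerate ALL occurrences of each pattern in ``record``.

    Overlapping and nested occurrences are all reported. The result is
    sorted by ``(start, pattern_name)``.
    """
    hits = []
    seq = record.sequence
    for pat in patterns:
        rx = _compiled_regex(pat.positions)
        wc = pat.wildcard_indices
        x_index = wc[0] if len(wc) == 1 else None
        for m in rx.finditer(seq):
            start = m.start()
            matched = m.group(1)
            x_res = matched[x_index] if x_index is not None else None
            hits.append(
                MotifHit(
                    protein_id=record.identifier,
                    pattern_name=pat.name,
                    start=start,
                    end=start + len(pat),
                    matched=matched,
                    x_residue=x_res,
                    x_minus1_residue=seq[start - 1] if start > 0 else None,
                    x_nonstandard=(x_res is not None and x_res not in STANDARD_RESIDUES),
                )
            )
    hits.sort(key=lambda h: (h.start, h.pattern_name))
    return hits


def extract_context(record: ProteinRecord, hit: MotifHit, flank: int = 10) -> ContextSlice:
    """Extract the hit's window of ``flank`` residues on each side, clipped.

    The consensus analyses use ``flank=10`` (motif plus the 10 residues
    before and after); the order/PPII position profiles use ``flank=20``.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    seq = record.sequence
    if not (0 <= hit.start < hit.end <= len(seq)):
        raise ValueError(
            f"hit [{hit.start}, {hit.end}) out of range for record "
            f"{record.identifier!r} of length {len(seq)}"
        )
    if seq[hit.start : hit.end] != hit.matched:
        raise ValueError(
            f"hit was not produced from record {record.identifier!r}: "
            f"sequence slice {seq[hit.start:hit.end]!r} != matched {hit.matched!r}"
        )
    wstart = max(0, hit.start - flank)
    wend = min(len(seq), hit.end + flank)
    return ContextSlice(
        hit=hit,
        flank=flank,
        window=seq[wstart:wend],
        left_truncated=flank - (hit.start - wstart),
        right_truncated=flank - (wend - hit.end),
    )


def classify_protein(hits: Sequence) -> tuple:
    """Classify one protein's hit list into ('PPxY'|'LPxY'|'neither', has_both).

    A protein with at least one PPxY hit is PPxY regardless of LPxY hits
    (categories are mutually exclusive so prevalence percentages sum to
    100); ``has_both`` preserves the overlap.
    """
    names = {h.pattern_name for h in hits}
    has_pp = PPXY.name in names
    has_lp = LPXY.name in names
    if has_pp:
        category = PPXY.name
    elif has_lp:
        category = LPXY.name
    else:
        category = "neither"
    return category, (has_pp and has_lp)


@dataclass(frozen=True)
class PrevalenceSummary:
    """Interactome-level PY-motif prevalence (counts and 1-decimal percents)."""

    n_total: int
    n_ppxy: int
    n_lpxy_only: int
    n_neither: int
    n_both: int
    pct_ppxy: float
    pct_lpxy: float
    pct_neither: float
    per_protein: pd.DataFrame = field(repr=False, compare=False, default=None)


def prevalence(records: Sequence) -> PrevalenceSummary:
    """Count and percentage of proteins with PPxY / LPxY-only / neither."""
    records = list(records)
    if not records:
        raise ValueError("prevalence requires at least one record")
    rows = []
    for rec in records:
        hits = scan(rec, PY_PATTERNS)
        category, has_both = classify_protein(hits)
        rows.append(
            {
                "protein_id": rec.identifier,
                "n_ppxy_hits": sum(h.pattern_name == PPXY.name for h in hits),
                "n_lpxy_hits": sum(h.pattern_name == LPXY.name for h in hits),
                "category": category,
                "has_both": has_both,
            }
        )
    table = pd.DataFrame(rows)
    n_total = len(records)
    n_ppxy = int((table["category"] == PPXY.name).sum())
    n_lpxy = int((table["category"] == LPXY.name).sum())
    n_neither = n_total - n_ppxy - n_lpxy
    return PrevalenceSummary(
        n_total=n_total,
        n_ppxy=n_ppxy,
        n_lpxy_only=n_lpxy,
        n_neither=n_neither,
        n_both=int(table["has_both"].sum()),
        pct_ppxy=round(100.0 * n_ppxy / n_total, 1),
        pct_lpxy=round(100.0 * n_lpxy / n_total, 1),
        pct_neither=round(100.0 * n_neither / n_total, 1),
        per_protein=table,
    )


def flip_first_residue(record: ProteinRecord) -> ProteinRecord:
    """P<->L flip control: convert each PPxY to LPxY and vice versa.

    The ORIGINAL sequence is scanned once for both canonical patterns and
    all first-residue substitutions are applied simultaneously from that
    scan (no rescan between edits, which could cascade on overlapping
    motifs). The identifier gains a ``_flipped`` suffix.
    """
    hits = scan(record, PY_PATTERNS)
    seq = list(record.sequence)
    for hit in hits:
        seq[hit.start] = "L" if hit.pattern_name == PPXY.name else "P"
    return ProteinRecord(
        identifier=record.identifier + "_flipped",
        sequence="".join(seq),
        description=record.description,
    )


@dataclass(frozen=True)
class ValidationCounts:
    """Detections among a labelled positive set (benchmark harness)."""

    n_reference_positive: int
    n_detected_of_positive: int
    n_missed: int
    table: pd.DataFrame = field(repr=False, compare=False, default=None)
    missing_ids: tuple = ()


def benchmark_against_labels(records: Sequence, positive_ids) -> ValidationCounts:
    """Tally how many labelled positives carry >=1 canonical PY hit.

    ``positive_ids`` not present among the records are reported in
    ``missing_ids`` rather than silently dropped.
    """
    by_id = {r.identifier: r for r in records}
    positive_ids = list(dict.fromkeys(positive_ids))
    missing = tuple(i for i in positive_ids if i not in by_id)
    rows = []
    for pid in positive_ids:
        if pid in by_id:
            hits = scan(by_id[pid], PY_PATTERNS)
            rows.append(
                {"protein_id": pid, "detected": bool(hits), "n_hits": len(hits)}
            )
    table = pd.DataFrame(rows, columns=["protein_id", "detected", "n_hits"])
    n_pos = len(table)
    n_det = int(table["detected"].sum()) if n_pos else 0
    return ValidationCounts(
        n_reference_positive=n_pos,
        n_detected_of_positive=n_det,
        n_missed=n_pos - n_det,
        table=table,
        missing_ids=missing,
    )
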