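"""Deterministic synthetic data with planted ground truth.

Generators for proteomes (background residues from a human-proteome-like
composition, optional proline-rich windows, PY motifs planted at target
prevalences), per-residue score tracks (bounded noise around buried /
exposed regime baselines with optional window shifts), ligase membership
tables, phospho annotation tables with prescribed class counts, and a
labelled benchmark set with a known detected / missed split. Every
generator is a pure function of its spec and seed.

Accidental motifs arising from the background ARE part of ground truth:
the generated records are rescanned and the full oracle hit table kept
(rejecting accidental motifs would bias the residue composition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import STANDARD_RESIDUES, ProteinRecord
from .scanner import LPXY, PPXY, PY_PATTERNS, MotifHit, scan
from .sets import MembershipTable, PhosphoAnnotation
from .tracks import TrackTable

#: Swiss-Prot-like average amino-acid composition (normalised on use).
HUMAN_AA_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: Track regime baselines (RSA-like scale).
REGIME_BASELINES = {"exposed": 0.6, "buried": 0.15, "moderate": 0.375}


def _normalised_freqs(freqs: Mapping[str, float]) -> tuple:
    letters = sorted(freqs)
    if not set(letters) <= set(STANDARD_RESIDUES):
        raise ValueError("background frequencies must cover standard residues only")
    probs = np.array([freqs[aa] for aa in letters], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("background frequencies must be non-negative and sum > 0")
    return np.array(letters), probs / probs.sum()


@dataclass
class ProteomeSpec:
    """Study conditions for a synthetic proteome.

    Lengths are log-normal (median ``length_median``, shape
    ``length_sigma``) clamped to [min_length, max_length]. Per protein a
    categorical draw assigns a planted motif class: PPxY with probability
    ``p_ppxy``, LPxY with ``p_lpxy``, else none. A ``prorich_fraction`` of
    proteins get a contiguous window redrawn with proline boosted to
    ``prorich_proline_freq``.
    """

    n: int
    p_ppxy: float = 0.33
    p_lpxy: float = 0.16
    length_median: float = 300.0
    length_sigma: float = 0.45
    min_length: int = 50
    max_length: int = 2000
    residue_freqs: Mapping[str, float] = field(default_factory=lambda: dict(HUMAN_AA_FREQS))
    prorich_fraction: float = 0.15
    prorich_proline_freq: float = 0.30
    prorich_window: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.p_ppxy, self.p_lpxy, self.prorich_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_ppxy + self.p_lpxy > 1.0:
            raise ValueError("p_ppxy + p_lpxy must be <= 1")
        if self.min_length < 4:
            raise ValueError("min_length must allow a 4-mer motif")
        _normalised_freqs(self.residue_freqs)


@dataclass
class GroundTruth:
    """Planted classes/positions plus the full oracle hit table (rescan)."""

    planted: dict
    prorich: dict
    hits: dict


def _draw_length(rng: np.random.Generator, spec: ProteomeSpec) -> int:
    raw = rng.lognormal(mean=math.log(spec.length_median), sigma=spec.length_sigma)
    return int(min(max(raw, spec.min_length), spec.max_length))


def _occupied(seq: str) -> list:
    rec = ProteinRecord("tmp", seq)
    return [(h.start, h.end) for h in scan(rec, PY_PATTERNS)]


def _plant_position(
    rng: np.random.Generator, seq: list, letters, probs, pattern_name: str
) -> tuple:
    """Choose a motif position avoiding existing PY occurrences.

    Resamples up to 100 times; if every draw collides the sequence is
    lengthened with background residues and the motif placed in the tail.
    Returns (seq, position).
    """
    taken = _occupied("".join(seq))
    n = len(seq)
    pos = None
    for _ in range(100):
        cand = int(rng.integers(0, n - 3))
        if all(cand + 4 <= s or cand >= e for s, e in taken):
            pos = cand
            break
    if pos is None:
        extra = rng.choice(letters, size=12, p=probs)
        seq = seq + list(extra)
        pos = len(seq) - 8
    x = str(rng.choice(letters, p=probs))
    motif = ("PP" if pattern_name == PPXY.name else "LP") + x + "Y"
    seq[pos : pos + 4] = list(motif)
    return seq, pos


def generate_proteome(spec: ProteomeSpec) -> tuple:
    """Generate (records, GroundTruth) under the spec; identical seed, identical output."""
    rng = np.random.default_rng(spec.seed)
    letters, probs = _normalised_freqs(spec.residue_freqs)
    boosted = dict(spec.residue_freqs)
    boosted["P"] = spec.prorich_proline_freq
    scale = (1.0 - spec.prorich_proline_freq) / sum(
        v for k, v in spec.residue_freqs.items() if k != "P"
    )
    for k in boosted:
        if k != "P":
            boosted[k] = spec.residue_freqs[k] * scale
    letters_b, probs_b = _normalised_freqs(boosted)

    records = []
    planted: dict = {}
    prorich: dict = {}
    hits: dict = {}
    for i in range(spec.n):
        ident = f"SYN{i + 1:05d}"
        length = _draw_length(rng, spec)
        seq = list(rng.choice(letters, size=length, p=probs))

        window = None
        if rng.random() < spec.prorich_fraction:
            w = min(spec.prorich_window, length)
            wstart = int(rng.integers(0, length - w + 1))
            seq[wstart : wstart + w] = list(rng.choice(letters_b, size=w, p=probs_b))
            window = (wstart, wstart + w)
        prorich[ident] = window

        u = rng.random()
        if u < spec.p_ppxy:
            seq, pos = _plant_position(rng, seq, letters, probs, PPXY.name)
            planted[ident] = (PPXY.name, pos)
        elif u < spec.p_ppxy + spec.p_lpxy:
            seq, pos = _plant_position(rng, seq, letters, probs, LPXY.name)
            planted[ident] = (LPXY.name, pos)
        else:
            planted[ident] = None

        rec = ProteinRecord(ident, "".join(seq))
        records.append(rec)
        hits[ident] = scan(rec, PY_PATTERNS)
    return records, GroundTruth(planted=planted, prorich=prorich, hits=hits)


def generate_tracks(
    records: Sequence[ProteinRecord],
    regime: str = "exposed",
    noise: float = 0.1,
    seed: int = 0,
    kind: str = "rsa",
    baseline: Optional[float] = None,
    shift_windows: Optional[Mapping[str, tuple]] = None,
    shift_delta: float = 0.0,
) -> TrackTable:
    """Per-residue tracks: bounded uniform noise around a regime baseline.

    ``regime`` picks the baseline (exposed 0.6, buried 0.15, moderate
    0.375) unless ``baseline`` overrides it. ``shift_windows`` (protein id
    -> (start, end)) adds ``shift_delta`` inside the window — used to
    emulate e.g. elevated disorder over proline-rich regions. Values are
    clipped to [0, 1]. Deterministic per seed.
    """
    if baseline is None:
        if regime not in REGIME_BASELINES:
            raise ValueError(
                f"unknown regime {regime!r}; expected one of {sorted(REGIME_BASELINES)}"
            )
        baseline = REGIME_BASELINES[regime]
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    tracks = {}
    for rec in records:
        values = baseline + rng.uniform(-noise, noise, size=len(rec))
        if shift_windows and rec.identifier in shift_windows:
            win = shift_windows[rec.identifier]
            if win is not None:
                values[win[0] : win[1]] += shift_delta
        tracks[rec.identifier] = np.clip(values, 0.0, 1.0)
    return TrackTable(tracks=tracks, kind=kind)


def generate_membership(
    k: int, n: int, overlap: float, seed: int = 0, set_names: Optional[Sequence[str]] = None
) -> MembershipTable:
    """Membership table: one uniform primary set per protein, plus each other
    set independently with probability ``overlap``.

    Under this scheme the expected multi-set fraction is
    1 - (1 - overlap)^(k - 1). Deterministic per seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    names = tuple(set_names) if set_names is not None else tuple(f"S{i+1}" for i in range(k))
    if len(names) != k:
        raise ValueError(f"expected {k} set names, got {len(names)}")
    rng = np.random.default_rng(seed)
    memberships = {}
    for i in range(n):
        primary = int(rng.integers(0, k))
        member_of = {names[primary]}
        for j in range(k):
            if j != primary and rng.random() < overlap:
                member_of.add(names[j])
        memberships[f"PROT{i + 1:05d}"] = frozenset(member_of)
    return MembershipTable(set_names=names, memberships=memberships)


def generate_phospho(
    n_both: int, n_either: int, n_none: int, seed: int = 0, max_sites: int = 10
) -> tuple:
    """Annotation table with prescribed both / either / none class counts.

    Returns (PhosphoAnnotation, ordered id list). 'both' proteins get >= 1
    pT and >= 1 pS site, 'either' exactly one kind, 'none' zero of each.
    """
    for v in (n_both, n_either, n_none):
        if v < 0:
            raise ValueError("class counts must be non-negative")
    rng = np.random.default_rng(seed)
    sites = {}
    ids = []
    i = 0
    for _ in range(n_both):
        i += 1
        pid = f"PH{i:05d}"
        sites[pid] = (int(rng.integers(1, max_sites + 1)), int(rng.integers(1, max_sites + 1)))
        ids.append(pid)
    for _ in range(n_either):
        i += 1
        pid = f"PH{i:05d}"
        count = int(rng.integers(1, max_sites + 1))
        sites[pid] = (count, 0) if rng.random() < 0.5 else (0, count)
        ids.append(pid)
    for _ in range(n_none):
        i += 1
        pid = f"PH{i:05d}"
        sites[pid] = (0, 0)
        ids.append(pid)
    return PhosphoAnnotation(sites=sites), ids


def generate_benchmark(
    n_positive: int = 82,
    n_with_motif: int = 69,
    seed: int = 0,
    length: int = 200,
) -> tuple:
    """Labelled positive set mirroring a proteome-array validation: the first
    ``n_with_motif`` records carry planted PY motifs, the rest are verified
    motif-free (resampled until clean).

    Returns (records, positive_ids).
    """
    if not 0 <= n_with_motif <= n_positive:
        raise ValueError("need 0 <= n_with_motif <= n_positive")
    rng = np.random.default_rng(seed)
    letters, probs = _normalised_freqs(HUMAN_AA_FREQS)
    records = []
    for i in range(n_positive):
        ident = f"REF{i + 1:04d}"
        if i < n_with_motif:
            seq = list(rng.choice(letters, size=length, p=probs))
            name = PPXY.name if rng.random() < 0.67 else LPXY.name
            seq, _ = _plant_position(rng, seq, letters, probs, name)
            records.append(ProteinRecord(ident, "".join(seq)))
        else:
            for _ in range(1000):
                seq = "".join(rng.choice(letters, size=length, p=probs))
                if not scan(ProteinRecord(ident, seq), PY_PATTERNS):
                    break
            else:  # pragma: no cover - ~impossible at this length
                raise RuntimeError("could not draw a motif-free sequence")
            records.append(ProteinRecord(ident, seq))
    return records, [r.identifier for r in records]
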