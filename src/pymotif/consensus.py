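"""Consensus matrices and combinatorial PY peptide library design.

Aligned context slices (motif plus flanks, aligned on motif start) are
summarised as a position probability matrix — the data behind a
probability-scaled sequence logo. Ranked residues at the x-1 and x columns
then drive a combinatorial peptide library on an 11-mer template scaffold
(TA x-1 [P|L] P x Y ATLG), the WW-domain binding screen's input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import STANDARD_RESIDUES
from .scanner import ContextSlice

#: Native ENaC-derived template peptide with its PY motif at positions 3-6.
NATIVE_TEMPLATE = "TAPPPAYATLG"


@dataclass
class PositionProbabilityMatrix:
    """Per-column residue probabilities over aligned context slices.

    ``counts`` is a (window_length x alphabet) integer frame; ``n_c`` the
    number of slices contributing a residue at each column (truncated
    slices contribute only where they have residues). Column probabilities
    are counts / n_c; columns with n_c == 0 are empty.
    """

    counts: pd.DataFrame = field(repr=False)
    n_c: np.ndarray
    flank: int
    motif_length: int

    @property
    def window_length(self) -> int:
        return 2 * self.flank + self.motif_length

    @property
    def probabilities(self) -> pd.DataFrame:
        denom = np.where(self.n_c > 0, self.n_c, 1)
        return self.counts.div(denom, axis=0)

    def column(self, index: int) -> dict:
        """Residue -> probability map (observed residues only) at one column."""
        if not 0 <= index < self.window_length:
            raise IndexError(f"column {index} out of range 0..{self.window_length - 1}")
        row = self.counts.iloc[index]
        n = self.n_c[index]
        return {aa: cnt / n for aa, cnt in row.items() if cnt > 0}

    @property
    def x_column(self) -> int:
        """Window column of the motif's wildcard (x) slot for 4-mer PY motifs."""
        return self.flank + 2

    @property
    def x_minus1_column(self) -> int:
        """Window column immediately N-terminal to the motif."""
        return self.flank - 1


def build_ppm(slices: Sequence[ContextSlice], flank: int = None) -> PositionProbabilityMatrix:
    """Build the PPM from context slices aligned on motif start.

    All slices must share one flank setting and one motif length; pass
    ``flank`` to assert the expected setting. Truncated slices contribute
    only to the columns where they have residues.
    """
    slices = list(slices)
    if not slices:
        raise ValueError("cannot build a PPM from an empty slice collection")
    flanks = {s.flank for s in slices}
    if len(flanks) > 1:
        raise ValueError(f"slices mix flank settings {sorted(flanks)}")
    got_flank = flanks.pop()
    if flank is not None and flank != got_flank:
        raise ValueError(f"slices have flank {got_flank}, expected {flank}")
    motif_lengths = {s.hit.end - s.hit.start for s in slices}
    if len(motif_lengths) > 1:
        raise ValueError(f"slices mix motif lengths {sorted(motif_lengths)}")
    motif_length = motif_lengths.pop()
    window_length = 2 * got_flank + motif_length

    alphabet = sorted({ch for s in slices for ch in s.window} | set(STANDARD_RESIDUES))
    counts = pd.DataFrame(
        0, index=range(window_length), columns=alphabet, dtype=int
    )
    for s in slices:
        for j, ch in enumerate(s.window):
            counts.at[s.left_truncated + j, ch] += 1
    n_c = counts.sum(axis=1).to_numpy()
    return PositionProbabilityMatrix(
        counts=counts, n_c=n_c, flank=got_flank, motif_length=motif_length
    )


def top_k_residues(ppm: PositionProbabilityMatrix, column: int, k: int) -> list:
    """Top-k (residue, probability) at a column, ties broken alphabetically.

    Returns fewer than ``k`` entries when fewer residues were observed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    col = ppm.column(column)
    if not col:
        raise ValueError(f"column {column} is empty (no contributing slices)")
    ranked = sorted(col.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


@dataclass(frozen=True)
class PeptideTemplate:
    """An 11-mer scaffold with substitutable x-1 and x slots.

    For the templates TA x-1 [P|L] P x Y ATLG the slots sit at 0-based
    positions 2 (x-1) and 5 (x), with the 4-mer motif at positions 3-6.
    """

    scaffold: str
    base: str = NATIVE_TEMPLATE
    x_minus1_index: int = 2
    x_index: int = 5
    motif_start: int = 3

    def __post_init__(self) -> None:
        if self.scaffold not in ("PPxY", "LPxY"):
            raise ValueError(f"scaffold must be PPxY or LPxY, got {self.scaffold!r}")
        if len(self.base) != 11:
            raise ValueError(f"template base must be 11 residues, got {len(self.base)}")
        if self.x_minus1_index == self.x_index:
            raise ValueError("x-1 and x slot indices must be distinct")
        for idx in (self.x_minus1_index, self.x_index):
            if not 0 <= idx < len(self.base):
                raise ValueError(f"slot index {idx} out of range")
        ms = self.motif_start
        if self.base[ms] != self.scaffold[0] or self.base[ms + 1] != "P" or self.base[ms + 3] != "Y":
            raise ValueError(
                f"template base {self.base!r} violates scaffold {self.scaffold} "
                f"fixed positions at motif start {ms}"
            )


#: Both scaffolds on the native template (LPxY swaps the first motif P for L).
DEFAULT_TEMPLATES = (
    PeptideTemplate(scaffold="PPxY", base="TAPPPAYATLG"),
    PeptideTemplate(scaffold="LPxY", base="TAPLPAYATLG"),
)


@dataclass(frozen=True)
class LibraryPeptide:
    """One designed peptide: scaffold, slot residues, core 5-mer, sequence."""

    name: str
    sequence: str
    scaffold: str
    x_minus1: str
    x: str
    core: str


@dataclass(frozen=True)
class PeptideLibrary:
    """Combinatorial peptide set: |scaffolds| x |x-1 set| x |x set| entries."""

    entries: tuple

    def __len__(self) -> int:
        return len(self.entries)

    def per_scaffold(self) -> dict:
        out: dict = {}
        for e in self.entries:
            out[e.scaffold] = out.get(e.scaffold, 0) + 1
        return out

    def cores(self) -> list:
        return [e.core for e in self.entries]


def _check_residues(residues, label: str) -> list:
    residues = list(residues)
    if not residues:
        raise ValueError(f"{label} residue set must be non-empty")
    for r in residues:
        if r not in STANDARD_RESIDUES:
            raise ValueError(f"{label} set: non-standard residue {r!r}")
    return residues


def design_library(
    x_minus1_set: Iterable[str],
    x_set: Iterable[str],
    templates: Sequence[PeptideTemplate] = DEFAULT_TEMPLATES,
) -> PeptideLibrary:
    """Cartesian product of slot residues per scaffold; no deduplication.

    With the 3 and 5 highest-probability residues at x-1 and x this yields
    15 variants per scaffold, 30 peptides in total. Entry names encode the
    scaffold and the core 5-mer (x-1 plus motif), e.g. ``PP_APPSY``.
    """
    x1 = _check_residues(x_minus1_set, "x-1")
    xs = _check_residues(x_set, "x")
    entries = []
    for tpl in templates:
        for a in x1:
            for b in xs:
                seq = list(tpl.base)
                seq[tpl.x_minus1_index] = a
                seq[tpl.x_index] = b
                seq = "".join(seq)
                core = seq[tpl.x_minus1_index : tpl.motif_start + 4]
                entries.append(
                    LibraryPeptide(
                        name=f"{tpl.scaffold[:2]}_{core}",
                        sequence=seq,
                        scaffold=tpl.scaffold,
                        x_minus1=a,
                        x=b,
                        core=core,
                    )
                )
    return PeptideLibrary(entries=tuple(entries))


LIBRARY_CSV_COLUMNS = ("name", "scaffold", "x_minus1", "x", "core", "sequence")


def export_library(library: PeptideLibrary, dest, format: str = "csv") -> int:
    """Write the library as FASTA (names as headers) or CSV; returns entry count."""
    if not library.entries:
        raise ValueError("cannot export an empty library")
    from .io import _as_handle

    if format == "fasta":
        with _as_handle(dest, "w") as fh:
            for e in library.entries:
                fh.write(f">{e.name}\n{e.sequence}\n")
    elif format == "csv":
        rows = [
            {
                "name": e.name,
                "scaffold": e.scaffold,
                "x_minus1": e.x_minus1,
                "x": e.x,
                "core": e.core,
                "sequence": e.sequence,
            }
            for e in library.entries
        ]
        df = pd.DataFrame(rows, columns=list(LIBRARY_CSV_COLUMNS))
        with _as_handle(dest, "w") as fh:
            df.to_csv(fh, index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown export format {format!r} (fasta or csv)")
    return len(library.entries)


def library_from_csv(source) -> PeptideLibrary:
    """Re-read a CSV written by :func:`export_library`."""
    from .io import _read_frame

    df = _read_frame(source)
    entries = tuple(
        LibraryPeptide(
            name=str(r["name"]),
            sequence=str(r["sequence"]),
            scaffold=str(r["scaffold"]),
            x_minus1=str(r["x_minus1"]),
            x=str(r["x"]),
            core=str(r["core"]),
        )
        for _, r in df.iterrows()
    )
    return PeptideLibrary(entries=entries)


def plot_logo(ppm: PositionProbabilityMatrix, dest) -> None:
    """Render the PPM as a probability-scaled stacked-bar logo (PNG/PDF).

    A rendering convenience only; the PPM itself is the canonical output.
    """
    from matplotlib.figure import Figure

    probs = ppm.probabilities
    fig = Figure(figsize=(max(4.0, 0.25 * ppm.window_length), 2.5))
    ax = fig.add_subplot(111)
    positions = np.arange(ppm.window_length)
    bottom = np.zeros(ppm.window_length)
    for aa in probs.columns:
        heights = probs[aa].to_numpy()
        if heights.sum() == 0:
            continue
        ax.bar(positions + 1, heights, bottom=bottom, width=0.85, label=aa)
        for pos, h, b in zip(positions, heights, bottom):
            if h > 0.08:
                ax.text(pos + 1, b + h / 2, aa, ha="center", va="center", fontsize=6)
        bottom += heights
    ax.set_xlabel("window position (1-based)")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(dest, dpi=150)
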