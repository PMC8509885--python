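"""Reading and writing the formats the tool touches.

FASTA sequences go through Biopython's SeqIO; the delimited tables
(ligase membership, phospho-site counts, functional categories, per-residue
score tracks, gene->accession maps) go through pandas with the delimiter
auto-detected from the header row (tab preferred if present, else comma).
"""

from __future__ import annotations

import logging
import os
import re
from contextlib import contextmanager
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .records import ProteinRecord
from .scanner import ContextSlice, MotifHit, compile_pattern

logger = logging.getLogger(__name__)

Readable = Union[str, Path, object]

# UniProt-style pipe header: db|ACCESSION|ENTRY_NAME
_UNIPROT_HEADER = re.compile(r"^[A-Za-z0-9]+\|([^|\s]+)\|\S*$")

#: Fixed column order of the slice report.
SLICE_COLUMNS = (
    "protein_id",
    "pattern",
    "start",
    "matched",
    "left_truncated",
    "right_truncated",
    "window",
)

#: Column order of the hits report written by the ``scan`` subcommand.
HIT_COLUMNS = (
    "protein_id",
    "pattern",
    "start",
    "end",
    "matched",
    "x",
    "x_minus1",
    "x_nonstandard",
)


@contextmanager
def _as_handle(source: Readable, mode: str = "r"):
    if isinstance(source, (str, Path)):
        with open(source, mode) as fh:
            yield fh
    else:
        yield source


@contextmanager
def atomic_write(path: Union[str, Path]):
    """Open ``path`` for writing via a temp file renamed into place on success."""
    path = Path(path)
    tmp = path.with_name(path.name + f".tmp{os.getpid()}")
    fh = open(tmp, "w")
    try:
        yield fh
        fh.close()
        os.replace(tmp, path)
    except BaseException:
        fh.close()
        tmp.unlink(missing_ok=True)
        raise


def _parse_identifier(raw_id: str) -> str:
    m = _UNIPROT_HEADER.match(raw_id)
    return m.group(1) if m else raw_id


def read_fasta(source: Readable) -> list:
    """Read FASTA into a list of :class:`ProteinRecord`, in input order.

    The identifier is the first whitespace-delimited token after ``>``;
    UniProt ``db|ACC|name`` headers are special-cased to the accession.
    Lowercase is uppercased; ``*`` stop characters are stripped with a
    warning. Empty input, duplicate identifiers and illegal characters
    raise ``ValueError``.
    """
    records = []
    seen = set()
    with _as_handle(source) as fh:
        for seq_rec in SeqIO.parse(fh, "fasta"):
            ident = _parse_identifier(seq_rec.id)
            if ident in seen:
                raise ValueError(f"duplicate FASTA identifier {ident!r}")
            seen.add(ident)
            seq = str(seq_rec.seq)
            if "*" in seq:
                logger.warning(
                    "record %s: stripping %d '*' stop character(s)",
                    ident,
                    seq.count("*"),
                )
                seq = seq.replace("*", "")
            desc = seq_rec.description
            if desc.startswith(seq_rec.id):
                desc = desc[len(seq_rec.id) :].strip()
            records.append(ProteinRecord(ident, seq, desc))
    if not records:
        raise ValueError("empty FASTA input: no records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], dest: Readable, width: int = 60) -> int:
    """Write records as FASTA (wrapped at ``width``); returns records written."""
    n = 0
    with _as_handle(dest, "w") as fh:
        for rec in records:
            header = rec.identifier
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# delimited tables


@dataclass(frozen=True)
class IdMap:
    """Gene-symbol -> accession map (case-preserving, unique keys)."""

    entries: dict

    def __post_init__(self) -> None:
        for gene, acc in self.entries.items():
            if not acc:
                raise ValueError(f"idmap: empty accession for gene {gene!r}")


def _sniff(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    return "\t" if "\t" in header else ","


def _read_frame(source: Readable) -> pd.DataFrame:
    with _as_handle(source) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError("empty table input")
    return pd.read_csv(StringIO(text), sep=_sniff(text))


def _require(df: pd.DataFrame, columns: Sequence[str], schema: str) -> dict:
    """Map required lowercase names to actual column labels; error if absent."""
    lookup = {str(c).strip().lower(): c for c in df.columns}
    missing = [c for c in columns if c not in lookup]
    if missing:
        raise ValueError(
            f"{schema} table: missing required column(s) {missing}; "
            f"expected header containing {list(columns)}"
        )
    return {c: lookup[c] for c in columns}


def read_table(source: Readable, schema: str):
    """Read a delimited table under one of the named schemas.

    Schemas and required (case-insensitive) columns:

    - ``idmap``: gene, accession -> :class:`IdMap`
    - ``phospho``: protein, pt, ps -> :class:`~pymotif.sets.PhosphoAnnotation`
    - ``membership``: first column = protein id, remaining columns are set
      names with 0/1 flags -> :class:`~pymotif.sets.MembershipTable`
    - ``functional``: protein, category -> dict category -> set of proteins
    - ``track``: protein, length, scores (semicolon-separated floats),
      optional kind -> :class:`~pymotif.tracks.TrackTable`

    Unknown columns are preserved in the frame but ignored by the parsers.
    """
    df = _read_frame(source)
    if schema == "idmap":
        cols = _require(df, ("gene", "accession"), schema)
        entries = {}
        for _, row in df.iterrows():
            gene = str(row[cols["gene"]])
            if gene in entries:
                raise ValueError(f"idmap: duplicate gene {gene!r}")
            entries[gene] = str(row[cols["accession"]])
        return IdMap(entries)
    if schema == "phospho":
        from .sets import PhosphoAnnotation

        cols = _require(df, ("protein", "pt", "ps"), schema)
        sites = {
            str(r[cols["protein"]]): (int(r[cols["pt"]]), int(r[cols["ps"]]))
            for _, r in df.iterrows()
        }
        return PhosphoAnnotation(sites=sites)
    if schema == "membership":
        from .sets import MembershipTable

        if df.shape[1] < 2:
            raise ValueError(
                "membership table: expected a protein-id column followed by "
                ">=1 set column"
            )
        id_col = df.columns[0]
        set_names = tuple(str(c) for c in df.columns[1:])
        memberships = {}
        for _, row in df.iterrows():
            member_of = frozenset(
                name for name in set_names if int(row[name]) != 0
            )
            memberships[str(row[id_col])] = member_of
        return MembershipTable(set_names=set_names, memberships=memberships)
    if schema == "functional":
        cols = _require(df, ("protein", "category"), schema)
        categories: dict = {}
        for _, row in df.iterrows():
            categories.setdefault(str(row[cols["category"]]), set()).add(
                str(row[cols["protein"]])
            )
        return categories
    if schema == "track":
        from .tracks import TrackTable

        import numpy as np

        cols = _require(df, ("protein", "length", "scores"), schema)
        kind_col = next(
            (c for c in df.columns if str(c).strip().lower() == "kind"), None
        )
        kinds = set(df[kind_col].astype(str)) if kind_col is not None else set()
        if len(kinds) > 1:
            raise ValueError(f"track table: mixed kind labels {sorted(kinds)}")
        tracks = {}
        for _, row in df.iterrows():
            pid = str(row[cols["protein"]])
            values = np.array(
                [float(v) for v in str(row[cols["scores"]]).split(";") if v != ""]
            )
            stated = int(row[cols["length"]])
            if len(values) != stated:
                raise ValueError(
                    f"track table: protein {pid!r} has {len(values)} values "
                    f"but stated length {stated}"
                )
            tracks[pid] = values
        return TrackTable(tracks=tracks, kind=(kinds.pop() if kinds else "other"))
    raise ValueError(
        f"unknown table schema {schema!r}; expected one of "
        "{membership, phospho, functional, track, idmap}"
    )


# ---------------------------------------------------------------------------
# slice and hit reports


def write_slices_csv(slices: Sequence[ContextSlice], dest: Readable) -> int:
    """Write the slice report (CSV, fixed column order; 1-based start).

    All slices must share one flank setting. Returns the number of data
    rows written (excluding the header).
    """
    slices = list(slices)
    flanks = {s.flank for s in slices}
    if len(flanks) > 1:
        raise ValueError(f"slices mix flank settings {sorted(flanks)}")
    rows = [
        {
            "protein_id": s.hit.protein_id,
            "pattern": s.hit.pattern_name,
            "start": s.hit.start + 1,
            "matched": s.hit.matched,
            "left_truncated": s.left_truncated,
            "right_truncated": s.right_truncated,
            "window": s.window,
        }
        for s in slices
    ]
    df = pd.DataFrame(rows, columns=list(SLICE_COLUMNS))
    with _as_handle(dest, "w") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")
    return len(rows)


def read_slices_csv(source: Readable) -> list:
    """Re-read a slice report into :class:`ContextSlice` objects.

    The flank is recovered per row from the window length and truncation
    counts; the embedded hit is reconstructed from the report fields (its
    x residue from the pattern's wildcard slot when there is exactly one).
    """
    df = _read_frame(source)
    got = [str(c) for c in df.columns]
    if got != list(SLICE_COLUMNS):
        raise ValueError(
            f"slice report: expected columns {list(SLICE_COLUMNS)}, got {got}"
        )
    out = []
    for _, row in df.iterrows():
        matched = str(row["matched"])
        window = str(row["window"])
        lt = int(row["left_truncated"])
        rt = int(row["right_truncated"])
        flank2 = lt + rt + len(window) - len(matched)
        if flank2 % 2:
            raise ValueError("slice report row implies a non-integer flank")
        start = int(row["start"]) - 1
        pattern = compile_pattern(str(row["pattern"]))
        wc = pattern.wildcard_indices
        x_index = wc[0] if len(wc) == 1 else None
        flank = flank2 // 2
        left_in_window = flank - lt
        hit = MotifHit(
            protein_id=str(row["protein_id"]),
            pattern_name=pattern.name,
            start=start,
            end=start + len(matched),
            matched=matched,
            x_residue=matched[x_index] if x_index is not None else None,
            x_minus1_residue=window[left_in_window - 1] if left_in_window > 0 else None,
        )
        out.append(
            ContextSlice(
                hit=hit,
                flank=flank,
                window=window,
                left_truncated=lt,
                right_truncated=rt,
            )
        )
    return out


def write_track_table(table, dest: Readable, sep: str = "\t") -> int:
    """Write a TrackTable in the ``track`` schema dialect; returns row count."""
    rows = [
        {
            "protein": pid,
            "length": len(values),
            "scores": ";".join(format(v, ".17g") for v in values),
            "kind": table.kind,
        }
        for pid, values in table.tracks.items()
    ]
    df = pd.DataFrame(rows, columns=["protein", "length", "scores", "kind"])
    with _as_handle(dest, "w") as fh:
        df.to_csv(fh, index=False, sep=sep, lineterminator="\n")
    return len(rows)


def write_membership(table, dest: Readable, sep: str = "\t") -> int:
    """Write a MembershipTable in the ``membership`` schema dialect."""
    rows = [
        {"protein": pid, **{name: int(name in member_of) for name in table.set_names}}
        for pid, member_of in table.memberships.items()
    ]
    df = pd.DataFrame(rows, columns=["protein", *table.set_names])
    with _as_handle(dest, "w") as fh:
        df.to_csv(fh, index=False, sep=sep, lineterminator="\n")
    return len(rows)


def read_id_list(source: Readable) -> list:
    """Read a plain id list (one identifier per line, blanks ignored)."""
    with _as_handle(source) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_hits(hits: Sequence[MotifHit], dest: Readable, sep: str = "\t") -> int:
    """Write a hits table (1-based inclusive start/end); returns row count."""
    rows = [
        {
            "protein_id": h.protein_id,
            "pattern": h.pattern_name,
            "start": h.start + 1,
            "end": h.end,
            "matched": h.matched,
            "x": h.x_residue or "",
            "x_minus1": h.x_minus1_residue or "",
            "x_nonstandard": h.x_nonstandard,
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    with _as_handle(dest, "w") as fh:
        df.to_csv(fh, index=False, sep=sep, lineterminator="\n")
    return len(rows)


def read_hits(source: Readable) -> list:
    """Re-read a hits table written by :func:`write_hits`."""
    df = _read_frame(source)
    hits = []
    for _, row in df.iterrows():
        x = str(row["x"]) if pd.notna(row["x"]) and str(row["x"]) != "" else None
        xm1 = (
            str(row["x_minus1"])
            if pd.notna(row["x_minus1"]) and str(row["x_minus1"]) != ""
            else None
        )
        hits.append(
            MotifHit(
                protein_id=str(row["protein_id"]),
                pattern_name=str(row["pattern"]),
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                matched=str(row["matched"]),
                x_residue=x,
                x_minus1_residue=xm1,
                x_nonstandard=bool(row["x_nonstandard"]),
            )
        )
    return hits
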