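"""Aggregation of per-residue score tracks over motifs.

Externally computed annotations — relative solvent accessibility (RSA),
disorder, polyproline-II propensity — arrive as one real value per residue.
This module averages them over motif windows, bins motif-mean RSA into
buried / moderate / high accessibility classes (cuts at 0.25 and 0.5),
builds position profiles over motif +/- flank windows (mean, sample SD, n
per position, clipped at termini), runs paired and Welch two-sample t-tests
and correlates numeric component tables as Pearson coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scanner import MotifHit

logger = logging.getLogger(__name__)

TRACK_KINDS = ("rsa", "disorder", "ppii", "other")

#: RSA cut below which a residue is conventionally "buried".
BURIED_THRESHOLD = 0.25
#: RSA cut above which accessibility is "high".
HIGH_THRESHOLD = 0.5


@dataclass
class TrackTable:
    """Per-protein score tracks (one value per residue) with a kind label."""

    tracks: dict
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"track kind {self.kind!r} not in {TRACK_KINDS}")
        self.tracks = {k: np.asarray(v, dtype=float) for k, v in self.tracks.items()}

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.tracks

    def __getitem__(self, protein_id: str) -> np.ndarray:
        return self.tracks[protein_id]


@dataclass(frozen=True)
class MotifWindowStat:
    """Mean score over one motif's residues."""

    hit: MotifHit
    mean: float


def motif_mean(track, hit: MotifHit) -> MotifWindowStat:
    """Arithmetic mean of the track values across the motif residues."""
    values = np.asarray(track, dtype=float)
    if not (0 <= hit.start < hit.end <= len(values)):
        raise ValueError(
            f"hit [{hit.start}, {hit.end}) out of range for track of length "
            f"{len(values)} (protein {hit.protein_id!r})"
        )
    return MotifWindowStat(hit=hit, mean=float(values[hit.start : hit.end].mean()))


def bin_accessibility(mean: float) -> str:
    """Bin a motif-mean RSA: buried (< 0.25), moderate ([0.25, 0.5]), high (> 0.5).

    The two boundary values fall in the moderate class. Values outside
    [0, 1] are allowed (binned by the same cuts) but warned about.
    """
    if not 0.0 <= mean <= 1.0:
        logger.warning("RSA value %g outside [0, 1]; binning by the same cuts", mean)
    if mean < BURIED_THRESHOLD:
        return "buried"
    if mean > HIGH_THRESHOLD:
        return "high"
    return "moderate"


@dataclass
class PositionProfile:
    """Per-position mean / sample SD / n over motif +/- flank windows.

    Window positions run 0..2*flank + motif_length - 1 (reported 1-based,
    e.g. 1-44 for flank 20 around a 4-mer motif). Positions clipped at the
    sequence termini contribute nothing (n decremented). SD uses the n-1
    denominator; it is 0 for a single contributor and NaN where n == 0.
    """

    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    flank: int
    motif_length: int

    @property
    def window_length(self) -> int:
        return 2 * self.flank + self.motif_length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.window_length + 1),
                "mean": self.means,
                "sd": self.sds,
                "n": self.ns,
            }
        )


def position_profile(
    tracks: TrackTable, hits: Sequence[MotifHit], flank: int = 20
) -> PositionProfile:
    """Align track values on motif start and average per window position.

    Hits whose protein lacks a track are skipped with a warning (external
    predictors routinely drop sequences); at least one usable hit is
    required. All hits must share one motif length.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("position_profile requires at least one hit")
    motif_lengths = {h.end - h.start for h in hits}
    if len(motif_lengths) > 1:
        raise ValueError(f"hits mix motif lengths {sorted(motif_lengths)}")
    motif_length = motif_lengths.pop()
    window = 2 * flank + motif_length

    columns = [[] for _ in range(window)]
    used = 0
    for hit in hits:
        if hit.protein_id not in tracks:
            logger.warning("no track for protein %s; hit skipped", hit.protein_id)
            continue
        values = tracks[hit.protein_id]
        if hit.end > len(values):
            raise ValueError(
                f"hit end {hit.end} beyond track length {len(values)} "
                f"for protein {hit.protein_id!r}"
            )
        used += 1
        for c in range(window):
            idx = hit.start - flank + c
            if 0 <= idx < len(values):
                columns[c].append(values[idx])
    if used == 0:
        raise ValueError("no hit had a matching track")

    means = np.full(window, np.nan)
    sds = np.full(window, np.nan)
    ns = np.zeros(window, dtype=int)
    for c, vals in enumerate(columns):
        ns[c] = len(vals)
        if vals:
            arr = np.asarray(vals)
            means[c] = arr.mean()
            sds[c] = arr.std(ddof=1) if len(vals) > 1 else 0.0
    return PositionProfile(
        means=means, sds=sds, ns=ns, flank=flank, motif_length=motif_length
    )


@dataclass(frozen=True)
class TestResult:
    """A two-sided t-test outcome."""

    statistic: float
    df: float
    pvalue: float
    kind: str


def paired_t_test(profile_a: PositionProfile, profile_b: PositionProfile) -> TestResult:
    """Paired t-test on the two profiles' position means.

    Pairs are formed position by position; positions where either profile
    has no contributors are dropped. Requires >= 2 usable pairs; df = n - 1.
    """
    if profile_a.window_length != profile_b.window_length:
        raise ValueError(
            f"profiles have different windows ({profile_a.window_length} vs "
            f"{profile_b.window_length})"
        )
    mask = (profile_a.ns > 0) & (profile_b.ns > 0)
    a = profile_a.means[mask]
    b = profile_b.means[mask]
    n = len(a)
    if n < 2:
        raise ValueError(f"paired t-test needs >= 2 position pairs, got {n}")
    if np.all(a == b):
        # zero difference everywhere: no evidence of a shift
        return TestResult(statistic=0.0, df=float(n - 1), pvalue=1.0, kind="paired")
    res = stats.ttest_rel(a, b)
    return TestResult(
        statistic=float(res.statistic),
        df=float(n - 1),
        pvalue=float(res.pvalue),
        kind="paired",
    )


def welch_t_test(values_a: Iterable[float], values_b: Iterable[float]) -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df, two-sided."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch t-test needs n >= 2 in each group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("welch t-test is degenerate: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        pvalue=float(res.pvalue),
        kind="welch",
    )


def correlate_table(table: pd.DataFrame, reference_column: str) -> dict:
    """Pearson r of every other numeric column against the reference column.

    Constant columns are reported as NaN (undefined correlation). Requires
    >= 3 rows and a non-constant reference.
    """
    if reference_column not in table.columns:
        raise ValueError(f"reference column {reference_column!r} not in table")
    numeric = table.select_dtypes(include=[np.number])
    if reference_column not in numeric.columns:
        raise ValueError(f"reference column {reference_column!r} is not numeric")
    if len(numeric) < 3:
        raise ValueError(f"correlation needs >= 3 rows, got {len(numeric)}")
    ref = numeric[reference_column].to_numpy()
    if np.all(ref == ref[0]):
        raise ValueError(f"reference column {reference_column!r} is constant")
    out = {}
    for col in numeric.columns:
        if col == reference_column:
            continue
        vals = numeric[col].to_numpy()
        if np.all(vals == vals[0]):
            out[col] = float("nan")
        else:
            out[col] = float(stats.pearsonr(vals, ref).statistic)
    return out
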