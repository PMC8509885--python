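# pymotif

PY-motif scanning and interactome context analysis for WW-domain biology.

Nedd4-family HECT E3 ubiquitin ligases pick their substrates mostly through
WW domains, which bind short linear **PY motifs** — `PPxY` or `LPxY`, where
x is any residue — in the interactor's primary sequence (or, independently,
phospho-Thr/Ser marks). Given proteome FASTA and ordinary delimited tables,
`pymotif` answers the questions that come up when you study this
recognition mode at interactome scale:

- **Scan**: every PPxY/LPxY (or custom pattern) occurrence in every
  sequence, overlapping hits included, with the x and x−1 residues.
- **Context**: motif ± flank slices, position probability matrices
  (probability-scaled consensus/logo data), motif-window means of
  per-residue score tracks (RSA, disorder, PPII propensity),
  buried/moderate/high accessibility binning at the 0.25/0.5 cuts, and
  ±20-residue position profiles with paired / Welch t-tests.
- **Prevalence**: fraction of an interactome with PPxY / only LPxY /
  neither, plus the P↔L first-residue flip control and a benchmark
  harness against labelled positive sets.
- **Design**: combinatorial PY peptide libraries on the
  `TA·x−1·[P|L]P·x·Y·ATLG` template scaffold from the consensus's
  top-ranked residues.
- **Sets**: exclusive (UpSet-style) interactome intersections,
  multi-ligase sharing, pT/pS phospho classification of non-PY
  interactors, functional-category fractions, and Pearson correlation of
  numeric component tables.
- **Simulate**: seeded generators for proteomes with planted motifs,
  score tracks, membership and phospho tables — every analysis is
  testable without any download.

It is a library first (`import pymotif`) with a thin `pymotif` CLI over it.

## Worked example

`toy.fasta` holds three proteins: the native WW-domain substrate peptide
`TAPPPAYATLG`, a synthetic interactor carrying both an LPxY and a PPxY,
and a motif-free negative.

```text
$ pymotif scan toy.fasta
protein_id  pattern  start  end  matched  x  x_minus1  x_nonstandard
ENaC        PPxY     4      7    PPAY     A  P         False
Q00001      LPxY     3      6    LPAY     A  S         False
Q00001      PPxY     9      12   PPAY     A  Q         False
```

One hit per motif occurrence (positions 1-based inclusive): the template's
single `PPAY` with x = A and x−1 = P, and both motifs of Q00001.

```text
$ pymotif prevalence toy.fasta
n_total  n_ppxy  n_lpxy_only  n_neither  n_both  pct_ppxy  pct_lpxy  pct_neither
3        2       0            1          1       66.7      0.0       33.3
```

Q00001 counts in the PPxY category (PPxY takes precedence when both motifs
occur; the overlap is kept in `n_both`), so 2/3 = 66.7% PPxY, 0% LPxY-only,
33.3% neither — the three categories always sum to 100%.

```text
$ pymotif flip toy.fasta | head -2
>ENaC_flipped beta-subunit PY peptide context
TAPLPAYATLG
```

The flip control turns each PPxY into LPxY (and vice versa) in place —
`TAPPPAYATLG` becomes `TAPLPAYATLG`, which rescans to exactly one LPxY hit.

```text
$ pymotif design --x1 A,E,P --x A,G,P,S,Y --out library.csv
$ head -3 library.csv
name,scaffold,x_minus1,x,core,sequence
PP_APPAY,PPxY,A,A,APPAY,TAAPPAYATLG
PP_APPGY,PPxY,A,G,APPGY,TAAPPGYATLG
```

Three x−1 residues × five x residues × two scaffolds = 30 peptides
(15 per scaffold), named by scaffold and core 5-mer; the A/S combination
gives `TAAPPSYATLG` (core `APPSY`) and the native `TAPPPAYATLG` is
reproduced by the P/A combination.

The same operations are available as functions:

```python
import pymotif as pm

rec = pm.ProteinRecord("ENaC", "TAPPPAYATLG")
[hit] = pm.scan(rec)                       # PPxY at 0-based start 3
ctx = pm.extract_context(rec, hit, flank=10)
lib = pm.design_library(["A", "E", "P"], ["A", "G", "P", "S", "Y"])
len(lib)                                    # 30
```

## Layout

- `src/pymotif/records.py` — sequence record type, alphabet
- `src/pymotif/io.py` — FASTA and delimited-table reading/writing
- `src/pymotif/scanner.py` — patterns, scanning, slices, prevalence,
  flip, benchmark
- `src/pymotif/consensus.py` — PPMs, residue ranking, peptide library
- `src/pymotif/tracks.py` — score-track aggregation, binning, profiles,
  t-tests, correlations
- `src/pymotif/sets.py` — intersections, phospho, functional fractions
- `src/pymotif/simulate.py` — seeded synthetic-data generators
- `src/pymotif/cli.py` — the `pymotif` command

See `docs/methods.md` for the underlying model, conventions (coordinate
systems, tie-breaks, threshold boundaries) and the synthetic-data
assumptions.
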