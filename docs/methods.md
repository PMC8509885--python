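# Methods

## The problem

WW domains of the Nedd4 family of HECT-type E3 ubiquitin ligases recognise
interactors mainly through two short linear motifs in the interactor's
primary sequence — the PY motifs PPxY and LPxY, where x is any residue —
or, independently of PY motifs, through phospho-threonine/phospho-serine
marks. `pymotif` implements the sequence side of this problem end to end:
exhaustive PY-motif detection, context characterisation (consensus
matrices, solvent-accessibility and disorder-track aggregation),
combinatorial peptide-library design from the consensus, and set-level
analyses of ligase interactomes.

## Motif model and scanning

A motif pattern is an ordered list of position constraints: a fixed
residue or a wildcard. The three built-ins are PPY = [P][P][Y],
PPxY = [P][P][*][Y] and LPxY = [L][P][*][Y]; arbitrary specs of the same
dialect ("uppercase residue or lowercase x", length >= 3, at least one
fixed position) compile the same way.

Scanning enumerates **all** occurrences, including overlapping and nested
ones (implemented as a look-ahead regular expression so adjacent and
overlapping matches are not swallowed; the test-suite oracle is an
independent naive every-window check). Design choices:

- Fixed positions match only their exact residue. The ambiguity/rare codes
  B, J, O, U, X, Z are accepted in sequences, never match a fixed
  position, and do match a wildcard; a hit whose x residue is such a code
  is flagged (`x_nonstandard`).
- Coordinates are 0-based half-open in the API, 1-based in written
  reports.
- For each hit the x residue (wildcard slot) and the x-1 residue (the
  residue immediately N-terminal to the motif) are recorded; x-1 is absent
  for a motif at position 0.

Context slices take the motif plus `flank` residues each side, clipped at
the termini with the clipped counts recorded (flank 10 for consensus work,
flank 20 for order/PPII-style profiles, giving the 44-position window).

## Classification, prevalence, flip control, benchmark

A protein is classified PPxY if it has >= 1 PPxY hit (whether or not it
also has LPxY hits), LPxY if it has only LPxY hits, else neither. The
categories are mutually exclusive so prevalence percentages sum to 100;
the PPxY-over-LPxY precedence is a deliberate tie-break and the overlap is
retained in a `has_both` flag and exact counts, so any alternative
convention can be recomputed. Percentages are reported to 1 decimal.

The flip control scans the original sequence once for both canonical
patterns and substitutes the first residue of every hit simultaneously
(P -> L for PPxY, L -> P for LPxY). Rescanning between edits could cascade
on overlapping motifs, so the transform is defined from the original scan;
it is an involution on sequences whose hits do not overlap (property
tested).

The benchmark harness marks a labelled positive as detected when it
carries >= 1 PPxY or LPxY hit. Ids absent from the supplied records are
reported in a `missing_ids` field and excluded from the tallies, keeping
detected + missed = scanned positives.

## Consensus matrices and library design

Aligned on motif start, slices accumulate into a position probability
matrix: per column, residue counts divided by the number of slices that
actually have a residue there (`n_c`). Truncated slices therefore
contribute per column instead of being discarded — motifs near termini
stay in the consensus. Probability (not information content) is the
canonical scale; a stacked-bar logo rendering is provided as a convenience
only. Ranking at a column is by probability with alphabetical tie-break.

The peptide library substitutes the x-1 and x slots of an 11-mer template
scaffold, TA·x-1·PP·x·Y·ATLG (or ...LP...), derived from a native
WW-domain substrate peptide TAPPPAYATLG; slots sit at 0-based positions 2
and 5, the motif at 3-6. The library is the full Cartesian product
scaffolds x x-1 set x x set with no deduplication, so 3 x-1 residues and 5
x residues give 15 peptides per scaffold, 30 in total. Every entry
rescans to a hit of its scaffold at position 3; a second overlapping hit
can arise only when the chosen slot residues themselves recreate the
motif (e.g. x-1 = P with x = Y on the PPxY scaffold), which the tests
account for explicitly.

## Score-track aggregation

Per-residue tracks (relative solvent accessibility, disorder, polyproline
II propensity — computed by external predictors and consumed here as
plain numbers) are averaged over each motif's residues. Motif-mean RSA is
binned buried (< 0.25), moderate ([0.25, 0.5]) or high (> 0.5); the
endpoints fall in the moderate class so the bins form a total partition
(the conventional descriptions "RSA < 0.25 buried" and
"0.25 < RSA < 0.5 moderate" leave the boundary values undefined).
Out-of-range values are binned by the same cuts with a warning.

Position profiles align track values on motif start over the
2·flank + motif-length window; positions clipped at termini contribute
nothing (n decremented). Dispersion is the sample SD (n−1 denominator; 0
for a single contributor, NaN for none). Two comparisons are supported,
both two-sided: a paired t-test on the two profiles' position means
(pairs formed position by position, df = n−1, positions without
contributors in either profile dropped; identical profiles return t = 0,
p = 1 by convention), and Welch's unequal-variance t-test with the
Welch–Satterthwaite df on whatever sample the caller supplies — position
means or pooled per-protein values; both pooling conventions are exposed
because either reading is defensible. Statistics come from
`scipy.stats`; the tests recompute both from the textbook formulas to
1e-9. Pearson correlation of numeric component tables against a reference
column (e.g. total binding energy) reports constant columns as NaN.

## Set analyses

Interactome membership tables yield exclusive intersection counts (UpSet
semantics: proteins whose membership equals exactly a given subset), for
all 2^k − 1 combinations, k capped at 12; exclusive counts sum to the
union size by construction and the multi-ligase fraction is proteins in
>= 2 sets over the union. Phospho classification splits an id set into
both (>= 1 pT and >= 1 pS site), either (exactly one kind) and none; ids
absent from the annotation table are classified none — absence of a
report is not a verified negative, but it is counted as such, matching
how phospho-site databases are used in practice. Functional fractions are
plain percentages at 2 decimals; prevalence and phospho percentages print
at 1 decimal.

## Synthetic data

The generators define the conditions everything is tested under:

- **Proteome** — residues drawn i.i.d. from a Swiss-Prot-like composition
  table (a uniform table is available); lengths log-normal with median
  300 aa, shape 0.45, clamped to [50, 2000]; 15% of proteins get a
  40-residue window redrawn with proline boosted to 0.30 to emulate
  proline-rich regions. Per protein one categorical draw plants a PPxY
  (probability 0.33) or LPxY (0.16) motif — the prevalence scale of
  Nedd4-family interactomes — at a uniform position, avoiding existing PY
  occurrences (up to 100 position resamples, then the sequence is
  lengthened). The planted x residue is drawn from the background.
  Accidental motifs arising from the background are **included** in the
  ground truth via a rescan; rejecting them would bias composition. They
  also mean recovered prevalence sits slightly above the planted rate
  (~1–2 points at these conditions), which the 3-binomial-SE recovery
  check accommodates.
- **Tracks** — bounded uniform noise around regime baselines (exposed
  0.6, buried 0.15, moderate 0.375, or an explicit baseline), optional
  additive shift inside designated windows, clipped to [0, 1].
- **Membership** — one uniform primary set per protein plus each other
  set independently with probability q; the expected multi-set fraction
  is 1 − (1 − q)^(k−1), which the tests verify against the measured
  fraction.
- **Phospho** — prescribed class counts (e.g. 128 both / 17 either /
  8 none) with random site counts.
- **Benchmark** — n labelled positives of which a chosen number carry
  planted motifs and the rest are verified motif-free (resampled until
  clean), mirroring a proteome-array validation with known truth.

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; determinism is asserted byte-for-byte on the
FASTA output. The synthetic data makes no attempt at real domain
architecture, disorder physics or phylogenetic correlation between
sequences — passing tests demonstrate correctness of the computations
under the stated statistical model, not predictive performance on real
proteomes.

## Problem sizes and numerical notes

The shipped checks run a 2,000-protein proteome for prevalence recovery
(3-binomial-SE band), a 5,000-protein draw for generator calibration,
1,000 random sequences against the naive scanning oracle, 100 random
fixtures for each t-test oracle, and a 4,000-protein membership table;
the full suite completes in well under a minute. PPM columns are checked
to sum to 1 within 1e-9; t statistics match the closed-form recomputation
within 1e-9. Ties in residue ranking break alphabetically; degenerate
t-test inputs (all-equal pairs, zero variance in both Welch groups, n < 2)
are defined or rejected explicitly as documented above.

## Known limitations

- Scanning is exact-match only; no position-weight-matrix scoring or
  mismatch tolerance.
- The tool consumes externally computed RSA/disorder/PPII tracks; it does
  not predict them, and no docking or binding-energy computation is
  included — component tables are only correlated.
- Isoforms are not expanded: each FASTA record is an independent protein,
  and whatever records are supplied form the analysis universe.
- The phospho analysis classifies database-style annotation counts; it
  does not scan sequence for phosphosite motifs.
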