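# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the test suite does and does not demonstrate.

## Problem and model

The classifier answers one question: given a protein sequence, is it likely
to be secreted as luminal cargo of exosomes? Exosome cargo is structurally
and functionally heterogeneous, with no known targeting motif, so the model
is deliberately knowledge-free: a random forest over global sequence
statistics. The forest's score for a query is its class-probability
estimate (mean of the per-tree class probabilities, which for fully grown
trees is essentially the fraction of trees voting "cargo"); a Y/N call is
made at a decision threshold of 0.5, the point where the forest's modal
vote flips.

The model is only applicable to the population it was trained on:
vertebrate proteins without a signal peptide or transmembrane region
(proteins with either can reach vesicles by other routes). Applicability is
enforced structurally — queries violating these conditions are answered
`NA`, not scored.

## Feature encodings

Five schemes, all computable from the sequence alone:

| scheme | length | content |
|---|---|---|
| AA | 20 | residue frequencies |
| DP | 400 | ordered overlapping dipeptide frequencies, denominator N−1 |
| PCP | 11 | per-property means of normalized residue scales |
| PCP_AA | 31 | PCP ++ AA |
| PCP_AA_DP | 431 | PCP ++ AA ++ DP |

Residue order is alphabetical (ACDEFGHIKLMNPQRSTVWY), dipeptides row-major
over it, PCP block first in combined schemes. The order carries no meaning
for a forest, but it is fixed and part of the feature contract so that
persisted models remain applicable.

The DP denominator N−1 makes each DP vector a probability distribution over
the 400 ordered pairs (sum exactly 1, asserted to 1e−9 in tests), matching
the standard dipeptide-composition definition. **Combined-length note:**
descriptions of this feature family in the literature sometimes quote 33
and 433 for the combined vectors; with 11 named properties, 20 residues and
400 dipeptides the exact concatenations have 31 and 431 components, and
exact concatenation is the contract implemented and tested here.

### Property scales

The 11 scales (average flexibility, residue volume, relative mutability,
net charge, optimized side-chain interaction parameter, polarity, designed
α-helix propensity, designed β-sheet propensity, amphiphilicity index,
modified Kyte–Doolittle hydrophobicity, aromaticity) ship as a TSV
(`exopred/data/property_scales.tsv`) with a source column, and are
min–max-normalized per scale to [0, 1] before averaging, so every PCP
component is bounded and a constant scale passes through exactly. The
numeric values were transcribed from the cited literature scales and may
deviate at the margin from other editions of the same scales; because the
normalization is affine per scale and random forests are invariant to
monotone per-feature transforms, small transcription differences do not
change the model family. Aromaticity, which has no single canonical scale,
is a binary indicator (1 for F/W/Y, 0 otherwise; histidine is excluded).
The table is versioned (`bundled-1`) and swappable — `read_scale_table`
accepts any 11-scale TSV, and the version travels with persisted models.

## Sequence sanitization

Input residues outside the 20-letter canonical alphabet are handled by
policy: `strict` (raise, naming residue and position), `drop_ambiguous`
(exclude the record, counted — the dataset-building default, favouring
training purity) and `map_ambiguous` (U→C, O→K, delete B/J/X/Z — the
prediction default, so user queries are never silently refused). All three
are idempotent (property-tested).

## Alignment and redundancy reduction

Percent identity comes from an optimal Needleman–Wunsch global alignment
with BLOSUM62, gap open 10, extension 0.5 (the first gap position costs the
open penalty, each further position the extension), end gaps penalized, and
is defined as identical columns divided by alignment length including gap
columns. Co-optimal alignments can differ in identity; the implementation
canonicalizes the input order so identity(a, b) = identity(b, a) exactly.
The test oracle is an independent C implementation (biotite) run with the
substitution matrix doubled and integer gap costs (−20, −1) — an exact 2×
rescaling chosen because that aligner truncates fractional gap penalties —
and oracle comparisons either use unique-optimum pairs (mutated copies) or
accept any co-optimal identity.

Dataset identity summaries cover all ordered non-self pairs (N×(N−1)
alignments, as dataset similarity is conventionally reported); identity is
symmetric, so each unordered pair is aligned once and counted twice, which
leaves the mean and the population sd unchanged. Summaries over more than
2,000 sequences are quadratic and require an explicit opt-in or a seeded
pair-sampling budget.

Redundancy reduction is greedy longest-first clustering (ties by id): each
sequence joins the first retained representative it exceeds the identity
threshold with, else founds a cluster. This mirrors the visitation order of
standard clustering tools but uses exact global identities rather than
k-mer pre-filters — at the scale this package targets, exact semantics
(no retained pair above the threshold, verified exhaustively in tests;
idempotence) are worth the quadratic cost. The threshold comparison is
strictly greater-than, so a pair at exactly the threshold is retained.

## Cross-validation and model selection

Stratified k-fold CV (default 10-fold) repeated r times (default 10), each
repeat reshuffling folds with a seed derived from the base seed via a
stable hash; every forest in the grid gets its own derived seed. Feature
encoding is strictly per-sequence and precedes the split, so no information
can leak across folds. Metrics are computed per fold and aggregated as mean
± sd over the r×k fold-level values — matching the "ACC ± sd" style of
reporting and making the sd interpretable as fold-to-fold dispersion.
Stratification is used because fold-level MCC and AUC are unstable when a
fold's class ratio drifts. A class smaller than the fold count is rejected
up front.

The tree-count grid defaults to the 31-value sweep 100–1,000 (step 50),
1,500–6,000 (step 500), 8,000, 10,000. `grid_select` takes the argmax of
the aggregate mean (ACC by default), breaking ties toward fewer trees, then
toward the simpler scheme (PCP < AA < PCP_AA < DP < PCP_AA_DP). Other
forest hyperparameters are the common defaults: √d features per split,
unlimited depth; they are recorded in the persisted bundle.

## Metrics

SE, SP, ACC and MCC are computed as exact fractions from confusion counts;
a measure with a zero denominator is returned as NaN with an `undefined`
flag rather than raising, so fold aggregation can skip it. The MCC
numerator is TP·TN − FP·FN with the standard symmetric denominator — the
only form consistent with MCC's −1…+1 interpretation (it is −1 on
all-wrong tables, verified in tests).

AUC is the Mann–Whitney statistic computed from mid-ranks, so tied scores
count half; this equals trapezoidal integration of the ROC curve over all
distinct thresholds (asserted to 1e−9 against both an explicit O(n²)
pair-counting oracle and sklearn's implementation).

## Synthetic data

The generator emulates the *statistical* shape of a two-class sequence
classification task, not exosome biology: no motifs, domains or real
proteome decoys. Two constructions:

- `aa_bias`: i.i.d. residues from class distributions that interpolate
  between one shared Dirichlet draw (bias 0) and near-disjoint preferred
  half-alphabets (bias 1). Signal lives in composition, so AA/PCP features
  see it.
- `dipeptide_bias`: first-order Markov chains whose transition matrices
  blend the uniform matrix with opposite cyclic-shift permutations. Both
  matrices are doubly stochastic, so the stationary residue distribution is
  uniform for both classes (marginals match within 0.01 total variation at
  n ≥ 500, asserted empirically) while transition structure diverges with
  bias — only DP features can see the signal. This isolates, in a
  verifiable construction, the qualitative finding that dipeptide
  composition is the strongest of the five schemes.

Defaults: 200+200 records, lengths 50–400 (protein-like, and long enough
that DP vectors are well populated; the generator refuses lengths below
30), bias 0.7, no annotation noise. `annotation_noise` flags a fraction of
records with one random gate-triggering condition to exercise curation and
gating. Everything is driven by one seed and reproducible bit for bit.

Passing tests on these data show the machinery is correct (encodings,
bookkeeping, no leakage, gates, selection); they say nothing about
attainable accuracy on real exosome data, where class signal is far weaker
and annotation quality dominates.

## Problem sizes used in tests

The suite runs on a single CPU in well under five minutes: CV sanity checks
use 200+200 separable records with 100-tree forests at 5 folds; the
label-shuffle null uses 250+250 records with pooled held-out scores (AUC
expected in [0.45, 0.55]); the transition-signal comparison uses 120+120
Markov records at 3 folds; tree-count stabilization is checked at a reduced
grid (5 vs 400 vs 800 trees over 5 seeds); redundancy reduction is verified
exhaustively on 48 sequences. These sizes are the package's chosen
desk-scale study conditions; the full 31-point × 5-scheme sweep on
thousands of real proteins is run through the same code paths via the CLI.

## Known limitations

- Real training data (thousands of curated vertebrate proteins) must be
  supplied by the user; bundled data are synthetic only.
- The exact numeric property-scale values used by other implementations of
  this feature family are not published; bundled values are faithful
  transcriptions but not certified copies.
- Global-alignment redundancy reduction is O(N²) alignments and intended
  for datasets up to a few thousand sequences.
- Forest probability estimates are uncalibrated; the 0.5 threshold is the
  modal-vote convention, not an optimized operating point.
- The NA gate trusts the annotation table; no signal-peptide or
  transmembrane prediction is performed in-package.
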