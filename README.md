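# exopred

Sequence-based prediction of protein secretion via exosomes.

Most secreted eukaryotic proteins carry an N-terminal signal peptide and
leave the cell through the ER/Golgi pathway. A large set of *leaderless*
proteins is instead exported unconventionally, notably as luminal cargo of
exosomes — 30–100 nm vesicles released when multivesicular bodies fuse with
the plasma membrane. Exosome cargo proteins have no recognizable sequence
motif, which makes their identification a natural machine-learning problem.
This package provides the full workflow for building and applying a
random-forest classifier of exosome-mediated secretion from sequence alone,
for bioinformaticians annotating secretomes or curating vesicle proteomics
data.

## What it computes

**Feature encodings.** Each protein sequence of length $N$ is translated
into a fixed-length vector under one of five schemes:

- `AA` (20): amino-acid composition, $f_r = \mathrm{count}(r)/N$;
- `DP` (400): dipeptide composition over the $N-1$ overlapping ordered
  pairs, $f_{rs} = \mathrm{count}(rs)/(N-1)$;
- `PCP` (11): per-property sequence means
  $P_i = \frac{1}{N}\sum_{n=1}^{N} p_i(a_n)$, where $p_i$ is the $i$-th of
  11 min–max-normalized amino-acid scales (flexibility, volume, mutability,
  net charge, side-chain interaction, polarity, designed helix/sheet
  propensities, amphiphilicity, modified Kyte–Doolittle hydrophobicity,
  aromaticity);
- `PCP_AA` (31) and `PCP_AA_DP` (431): exact concatenations of the blocks.

**Dataset curation.** Training sets keep only vertebrate, non-transmembrane,
leaderless proteins (annotations supplied as a TSV standing in for
UNIPROT/SignalP/TMHMM lookups), then remove redundancy so that no retained
pair exceeds 80% identity under Needleman–Wunsch global alignment (BLOSUM62,
gap open 10, extend 0.5; identity = identical columns / alignment length).

**Model and selection.** A random forest (scikit-learn, $\sqrt{d}$ features
per split) is trained per scheme over a tree-count grid (100–10,000); models
are compared by stratified tenfold cross-validation repeated ten times,
reporting mean ± sd of ACC, AUC and MCC over fold-level values:

$$SE = \frac{TP}{TP+FN},\quad SP = \frac{TN}{TN+FP},\quad
ACC = 100\cdot\frac{TP+TN}{TP+FP+TN+FN},$$
$$MCC = \frac{TP\cdot TN - FP\cdot FN}
{\sqrt{(TN+FN)(TP+FN)(TN+FP)(TP+FP)}},$$

with AUC the area under the ROC curve ($SE$ vs $1-SP$), computed by
Mann–Whitney pair counting (= trapezoidal integration).

**Gated prediction.** Queries flagged non-vertebrate, signal-peptide-bearing
or transmembrane are reported as `NA` (the model does not apply to them);
everything else receives a score in [0, 1] and a `Y`/`N` call at 0.5.

A seeded synthetic-data generator produces two-class datasets whose signal
lives either in residue composition or — with matched marginals — only in
residue *transitions*, so the added value of dipeptide features is testable
without downloading real data.

## Worked example

```python
from exopred import ExosomeSecretionModel, SyntheticConfig, generate

records, _ = generate(SyntheticConfig(n_pos=150, n_neg=150,
                                      bias_strength=0.12, seed=42))
model = ExosomeSecretionModel(records, scheme="DP")
results = model.fit(n_trees=200, seed=0, n_folds=5, n_repeats=2)
print(results.summary())
```

```
Exosome secretion random-forest model
==============================================
feature scheme       DP
trees                200
training proteins    150 exosome / 150 non-exosome
decision threshold   0.5
scale set            bundled-1
----------------------------------------------
cross-validation     5-fold x 2 repeats
ACC (%)              88.50 ± 3.80
AUC                  0.949 ± 0.023
MCC                  0.773 ± 0.076
SE                   0.873 ± 0.058
SP                   0.897 ± 0.064
```

The CV block reads as usual: on held-out folds the dipeptide model called
88.5% of proteins correctly (sd over the 10 fold-level values), ranked
positives above negatives with probability 0.949, and `results.predict(...)`
then returns per-protein scores with their Y/N calls. Real datasets enter
the same way via `ExosomeSecretionModel.from_fasta(positives, negatives)`.

The same workflow is scriptable from the shell:

```sh
exopred make-synthetic --n-pos 200 --n-neg 200 --bias 0.7 --out-dir data/
exopred curate --positives data/positives.fasta --negatives data/negatives.fasta \
               --annotations data/annotations.tsv --identity 80 --out-dir curated/
exopred cv-sweep --positives curated/positives.curated.fasta \
                 --negatives curated/negatives.curated.fasta \
                 --schemes AA,DP --trees 100,500,1000 --out cv.tsv
exopred train --positives curated/positives.curated.fasta \
              --negatives curated/negatives.curated.fasta \
              --scheme DP --trees 3000 --model-out model.joblib
exopred predict --fasta queries.fasta --annotations ann.tsv --model model.joblib
```

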