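# Methods

## Problem and model

Glutarylation is a lysine post-translational modification. The predictor
treats every lysine in a protein as a candidate site and classifies it from
the evolutionary context of its flanking residues, encoded by a PSI-BLAST
position-specific scoring matrix (PSSM). The modeling assumptions are:

- the discriminative signal lives in the residues flanking the site, so a
  fixed window of `2ξ + 1` residues centered on the lysine suffices;
- substitution-score *co-occurrence* between amino-acid pairs across the
  window (a bigram/Gram statistic) is more informative than raw per-position
  scores, and is position-count invariant after column standardization;
- a small randomized tree ensemble is enough to exploit the 210-dimensional
  descriptor once classes are roughly balanced.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `xi` | 10 | flank length; window = 21 residues, the widely used size for lysine-PTM predictors |
| `identity_threshold` | 0.40 | greedy negative-redundancy cutoff (fraction of identical window positions) |
| oversampling scalars | 1.0001, 1.0005 | element-wise multipliers applied to each positive training vector |
| `test_fraction` | 0.10 | independent test split |
| CV folds | 10 | stratified cross-validation |
| classifier | extra_trees | 10 trees, `min_samples_split = 2` |

**Windows.** One window per lysine; termini padded with the dummy residue
X. Annotated positions must carry K (anything else is an annotation error,
reported with protein and position). Residues outside the 20-letter
alphabet (B, Z, J, U, O) are mapped to X with a logged warning so the
20-column feature space is preserved. All positions in I/O are 1-based.

**Profiles.** The PSI-BLAST ASCII parser keeps only the first 20 numeric
columns of each position row — the log-odds block, which matches the
substitution-score semantics of the features — and ignores the
weighted-percentage block and trailing statistics. Padding rows (X) score
zero in all columns, the neutral log-odds value. Two acquisition modes
exist because upstream practice varies: one profile per 21-mer peptide
(default) or one per protein sliced per window; for identical score rows
the two are equivalent (tested). PSI-BLAST itself (3 iterations, E = 0.001
against a non-redundant database) is documented as a command template only
and never executed.

**Features.** Column z-scores use the population standard deviation
(divide by L). Zero-spread columns standardize to zero rather than NaN,
which keeps degenerate windows (e.g. heavy X padding) inside the fixed
210-length contract. The Gram matrix is symmetrized exactly
(`(G + Gᵀ)/2`) to absorb float round-off before the vectorizer, which
rejects asymmetry beyond 1e-8 as a broken upstream step. The vectorization
order — 20 diagonal entries, then the 190 strict-upper-triangle entries
row-major — is one of several equivalent fixed orders; determinism is what
matters for model reuse, and `unvectorize_symmetric` makes the mapping an
exact bijection.

**Dataset assembly.** Fixed order: annotate → window → reduce negative
redundancy → split → oversample the training part. The redundancy filter
is a greedy single-linkage pass in input order (a stand-in for CD-HIT
clustering): a negative window is dropped when its ungapped identity with
any retained negative exceeds the threshold; X–X counts as a match;
positives always pass. Oversampling is plain element-wise multiplication
of each positive vector by each scalar; the copies sit within 5e-4
relative distance of their sources and are flagged `augmented`, and the
split rejects already-augmented data so augmented rows can never reach a
test partition. The split is stratified by label by default (disable with
`stratify=False`) and sized as `round(test_fraction · n)` via a seeded
generator with largest-remainder class allocation.

**Classifier.** Extra-Trees with 10 trees is the primary model; the
registry also carries random-forest (`max_depth=2`, `random_state=42`,
300 trees), AdaBoost (300), XGBoost (300), LightGBM (`num_leaves=31`, 40
estimators, library-default learning rate) and a one-hidden-layer MLP
(100 ReLU units, `alpha=1`, `max_iter=1000`, initial learning rate 0.001).
Scores are the ensemble's positive-class probability; the decision
threshold is 0.5 — the natural operating point once training classes are
balanced. Gini feature importances are normalized to sum to one and are
only defined for tree ensembles.

**Evaluation.** ACC/SN/SP as percentages, MCC with a zero-denominator →
0 rule, F1 with PR+RE = 0 → 0. Cross-validation uses stratified folds
(723-scale positive counts across 10 folds would otherwise risk degenerate
folds) with oversampling applied inside each training fold only. Headline
CV metrics come from pooled out-of-fold predictions, which keep MCC
well-defined for small folds; per-fold accuracies are attached for
inspection. ROC groups tied scores at a single threshold step and the
trapezoidal AUC therefore equals the Mann–Whitney pairwise statistic
(verified against a brute-force oracle to 1e-12).

## Synthetic benchmark

The generator emulates the two inputs the real pipeline needs — annotated
proteins and class-conditional profiles — without PSI-BLAST or downloads.
Sequences are i.i.d. draws with lysine boosted to 8% so windows are
plentiful; each lysine is annotated positive with probability `site_rate`.
Profiles are Gaussian (SD `noise_sd`, default 1) around an
identity-favoring baseline (+6 match / −1 mismatch, values rounded to the
integer-ish log-odds range of real PSSMs); for positive windows the means
of the designated `signal_columns` (default the first four) are raised by
`effect_size` (default 3) in the five rows centered on the site — center
±2 — because flanking residues are where a real modification signal would
sit, which also makes feature-importance recovery a meaningful check.
Per-window RNG streams are derived from the window's provenance, so
generation order never affects output and runs are byte-reproducible.

What the generator does *not* emulate: real evolutionary conservation
structure, inter-column score correlations of genuine PSSMs, homology
between proteins, or realistic class imbalance severity. Passing the
synthetic recovery tests therefore shows the pipeline is wired correctly
and can detect a planted class-conditional signal of the stated size — not
that any particular accuracy will transfer to curated benchmark data.

## Problem sizes used in checks

The recovery experiments run at 200 windows per class (10-fold CV) for the
strong-effect check, 40 per class over 20 seeds for the null-effect AUC
interval, and 100 per class over 10 seeds for importance recovery; these
sizes give stable statistics while keeping the full suite fast on one CPU.
The importance criterion counts a seed as a success when at least 5 of the
10 descriptor entries induced by the four signal columns (their 4 Gram
diagonals plus 6 pairs) rank in the top decile of the 210 importances.

## Known limitations

- The greedy identity filter is order-dependent and single-linkage; it is
  the package's correctness reference, not a CD-HIT replacement for
  publication-grade redundancy control.
- Scalar-multiplication oversampling adds near-duplicates, not new
  information; it rebalances the loss rather than enriching the minority
  class, and tree ensembles see the copies as almost identical points.
- Per-peptide PSSMs of 21-mers are statistically weak in real PSI-BLAST
  practice; the per-protein slicing mode is usually preferable with real
  data.
- The MLP registry entry exposes no feature importances and is not tuned.
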