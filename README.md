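# glutsite

Prediction of lysine glutarylation sites from bi-peptide evolutionary
features of PSSM profiles.

Glutarylation is a post-translational modification in which a glutaryl
group attaches to a lysine residue, with roles in metabolic regulation and
mitochondrial function. Experimentally mapping modified lysines is slow and
expensive, so sequence-based predictors are used to triage candidate sites.
`glutsite` is a library plus command-line tool for building and evaluating
such a predictor: it is aimed at bioinformaticians who have annotated
protein sequences and PSI-BLAST profiles (or who want to exercise the whole
pipeline on synthetic data first).

## Method

Every lysine K in a protein defines a candidate site, represented by a
peptide window of `2ξ + 1` residues centered on the K (default `ξ = 10`,
window length 21), padded with the dummy residue X at protein termini.
Each window is described by a PSSM — an `L × 20` matrix of per-position
substitution scores `É(i→j)` from PSI-BLAST. The feature construction is:

1. **Column standardization.** Each amino-acid column j is z-scored over
   the L window positions with the population standard deviation,
   `E(i→j) = (É(i→j) − mean_j) / SD_j`; constant columns map to zero.
2. **Gram matrix.** `G = MᵀM` of the standardized `L × 20` matrix M — a
   symmetric positive semi-definite `20 × 20` matrix (400 elements) whose
   entry `(a, b)` measures how substitution propensities toward amino
   acids a and b co-vary across the window.
3. **Triangular vectorization.** Symmetry leaves 210 informative values:
   the 20 diagonal entries, then the 190 strict upper-triangle entries
   row-major. This 210-vector `P_evo = (Θ₁E, …, Θ₂₁₀E)` is the input to
   the classifier.

Negative windows (unannotated lysines) vastly outnumber positives, so the
training pipeline (a) greedily removes negative windows above 40% pairwise
identity with an already retained negative, and (b) after the train/test
split, oversamples each positive training vector by multiplying it
element-wise with the scalars 1.0001 and 1.0005, tripling the positive
count (723 positives would become 2169) while leaving the test partition
untouched. The default classifier is an Extra-Trees ensemble (10 trees,
`min_samples_split = 2`); random-forest, AdaBoost, MLP, XGBoost and
LightGBM configurations are registered for comparison. Evaluation reports
accuracy, sensitivity, specificity as percentages, MCC, F1, ROC and AUC,
from stratified 10-fold cross-validation (oversampling applied inside each
training fold only) and from the held-out independent test set.

## Worked example

The synthetic generator emulates annotated proteins and class-conditional
profiles, so the whole pipeline runs without PSI-BLAST or any download:

```sh
glutsite simulate --out demo --n-proteins 30 --protein-length 150 \
    --site-rate 0.3 --seed 42
# wrote 30 proteins, 354 windows -> demo
glutsite featurize --windows demo/windows.fasta --profiles demo/profiles \
    --out demo/features.csv
# wrote 354 x 210 features -> demo/features.csv
glutsite train --features demo/features.csv --out demo/run --seed 42
# test ACC=82.9% SN=60.0% SP=92.0% MCC=0.559 F1=0.667 AUC=0.948
glutsite cv --features demo/features.csv --out demo/cv.json --seed 42
# 10-fold CV ACC=92.4% SN=79.6% SP=97.3% MCC=0.805 AUC=0.942
```

`simulate` writes proteins (FASTA), site annotations (TSV), windows
(FASTA) and one profile CSV per window. `train` holds out a random 10%
test set, balances the training part by oversampling, fits Extra-Trees and
prints the independent-test metrics (here only 35 windows — 10 of them
positive — are held out, so SN moves in ~10% steps; the pooled 10-fold CV
line is the steadier estimate). An AUC near 0.95 means a randomly chosen
glutarylated window outscores a randomly chosen unmodified one ~95% of the
time under the simulation's effect size of 3.

Real profiles are consumed either one per 21-mer peptide (default) or one
per protein, sliced per window (`--mode per-protein`); both PSI-BLAST
ASCII PSSM files (`*.pssm`) and plain CSV profiles are accepted.

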