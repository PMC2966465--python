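# metaroc

ROC/AUC-ranked **metagene** classification of two-class gene-expression data,
with a leakage-safe evaluation protocol. The package is aimed at
transcriptomics analysts who need a simple, robust, weight-free classifier for
binary phenotypes (e.g. invasive vs. non-invasive tumours) from bulk
microarray or log-scale RNA expression matrices — and at methodologists who
want a clean reference implementation of AUC-based feature selection with
nested cross-validation.

## The method

For a binary phenotype *z* ∈ {0, 1} and a per-gene covariate *x*, the area
under the empirical ROC curve is computed through the Mann–Whitney identity

    AUC = U / (n₁ n₀),   U = R₁ − n₁(n₁+1)/2,

with midranks, so a tie between a positive and a negative sample counts ½.
A gene negatively associated with the phenotype has AUC < ½; its performance
is the **oriented AUC** max(AUC, 1 − AUC), and its **sign** is −1 (its
expression is negated before averaging) or +1 otherwise.

A signature of size *k* is the top *k* genes by oriented AUC. The **metagene**
of a sample is the unweighted arithmetic mean of the sign-corrected
expression of the signature genes

    m(s) = (1/k) Σ_g sign_g · x_{g,s}.

The decision threshold *t* maximises training accuracy over all splits of the
samples sorted by metagene value and is placed at the midpoint of the two
border samples; a sample with m(s) > t is called class 1. There are no
per-gene weights — the simplicity is the point.

Evaluation uses **leave-one-out cross-validation with feature selection
repeated inside every fold** (ranking, signs and threshold are all re-derived
on the n−1 retained samples), pooled into one confusion table per signature
size, summarised as the prevalence-independent **balanced accuracy**
(sensitivity + specificity)/2. For independent cohorts the **gene-transfer
protocol** carries over only the gene identities: signs and threshold are
re-learned per fold on the validation cohort itself. Null diagnostics
(per-gene AUC envelopes on randomised data, informative-gene excess,
cross-cohort AUC concordance, Shapiro/SD profiling) quantify how much of a
dataset's ranking is signal rather than chance.

## Worked example

```python
from metaroc import (SyntheticSpec, generate_two_class, train, loocv,
                     randomize_dataset, null_auc_interval,
                     informative_fraction, rank_genes)

spec = SyntheticSpec(n_genes=2000, n_informative=50, effect_size=1.5,
                     n_pos=30, n_neg=30, seed=7)
matrix, labels, truth = generate_two_class(spec)

model = train(matrix, labels, xgenes=50)
print("threshold:", round(model.threshold, 3),
      "training accuracy:", model.training_accuracy)

report = loocv(matrix, labels, [10, 50, 200])
print(report.summary().to_string(index=False))

null = null_auc_interval(randomize_dataset(matrix, seed=1), labels)
aucs = rank_genes(matrix, labels.to_numpy())["auc"]
outside, excess = informative_fraction(aucs, null)
print(f"null 99% envelope: [{null.lower:.3f}, {null.upper:.3f}]")
print(f"fraction outside: {outside:.3f}  informative excess: {excess:.3f}")
```

prints

```
threshold: 0.719 training accuracy: 1.0
 xgenes  tp  fp  tn  fn  sensitivity  specificity  balanced_accuracy
     10  30   0  30   0          1.0          1.0                1.0
     50  30   0  30   0          1.0          1.0                1.0
    200  30   0  30   0          1.0          1.0                1.0
null 99% envelope: [0.314, 0.684]
fraction outside: 0.041  informative excess: 0.030
```

Fifty genes planted at a 1.5-SD class shift in a 30 vs 30 design are easy for
the metagene: held-out balanced accuracy is 1.0 at every signature size. The
null envelope from the randomised copy of the same matrix brackets 0.5, and
4.1% of the real genes fall outside it — a 3.0% excess over the 1% expected
by chance, which bounds the number of genuinely informative genes.

The same workflows are available from the shell:

```sh
metaroc simulate --spec spec.json --seed 7 --out-prefix sim
metaroc train   --data sim_expr.tsv --labels sim_labels.tsv --xgenes 50 --out model.json
metaroc predict --model model.json --data sim_expr.tsv --out calls.tsv
metaroc cv      --data sim_expr.tsv --labels sim_labels.tsv --xgenes 5:200:5 --out cv.tsv
metaroc null    --data sim_expr.tsv --labels sim_labels.tsv --seed 17 --out null.json
metaroc validate --model model.json --data other_expr.tsv --labels other_labels.tsv --out val.tsv
```

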