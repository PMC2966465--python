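# Methods

## Model and procedure

The classifier is univariate in a derived covariate: the metagene, an
unweighted mean of sign-corrected expression over the top-ranked genes.
Training consists of four deterministic steps given a genes × samples matrix
and binary labels:

1. **Per-gene AUC.** Computed through the Mann–Whitney rank identity with
   midranks, so ties between a positive and a negative sample count ½ of a
   concordant pair. This equals the trapezoidal area under the empirical ROC
   curve and is invariant under strictly increasing transforms of the
   covariate.
2. **Orientation and ranking.** Each gene's performance is
   max(AUC, 1 − AUC); genes with AUC < 0.5 get sign −1. An AUC of exactly
   0.5 keeps sign +1 — an arbitrary but deterministic convention. Genes are
   sorted by oriented AUC descending; ties are broken by gene identifier
   (lexicographic), so the ranking is independent of input row order. This
   differs from implementations that inherit input order under ties; we
   prefer reproducibility.
3. **Metagene.** The mean of sign-corrected expression over the first
   `xgenes` ranked genes. No per-gene weights.
4. **Threshold.** Candidate thresholds are the midpoints between consecutive
   distinct metagene values, plus sentinels below the minimum and above the
   maximum (offset: half the smallest positive gap; 1 if all values are
   equal, which keeps thresholds finite and serialisable). The threshold
   maximises *unbalanced* training accuracy under the strict rule
   "metagene > t ⇒ class 1"; equality at the threshold predicts class 0.
   Accuracy ties are broken by higher sensitivity, then by the larger
   threshold. Balanced accuracy is used only for evaluation, never for
   fitting.

## Evaluation protocol

LOOCV re-derives ranking, signs and threshold inside every fold on the n−1
retained samples; the held-out predictions are pooled into one global
confusion table per signature size (not averaged per fold) and summarised as
balanced accuracy (sensitivity + specificity)/2, which is independent of
class prevalence. Fold viability (≥ 2 samples per class overall) is enforced
up front rather than by skipping degenerate folds.

The gene-transfer protocol for independent cohorts fixes only gene
identities. Per-gene signs are part of the discarded AUC information, so they
are re-derived — per validation fold, together with the threshold — on that
fold's n−1 samples. Signature genes absent from the validation matrix are
dropped with a warning and recorded. Prediction of new samples with a stored
model supports a strict mode (error on missing genes, the default) and an
intersect mode (re-average over the available genes) for cross-platform use.

## Null diagnostics

Randomised datasets replace each gene's row with Gaussian draws matching that
gene's observed mean and SD. Per-gene moments (rather than whole-matrix) are
the default because they preserve the marginal structure the envelope is
compared against; a `per_gene=False` switch gives the global alternative. A
zero-SD gene becomes a constant row. The null envelope is the empirical
central interval (order-statistic quantiles with linear interpolation —
stated because quantile conventions differ) of the per-gene AUCs; at
coverage 0.99 and a balanced 56-sample design it is ≈ [0.30, 0.70], matching
the normal approximation 0.5 ± z₀.₉₉₅ · √((n₀+n₁+1)/(12 n₀ n₁)). The
informative excess is the fraction of real-data AUCs outside the envelope
minus the nominal (1 − coverage) false-discovery share. Normality profiling
uses the Shapiro–Wilk test (at most 5000 samples per test, the common
implementation limit); constant genes have an undefined p-value and are
reported missing.

## Preprocessing transforms

- Duplicate gene identifiers are merged by the element-wise median;
  idempotent; merge precedes imputation-based analyses (the order is a
  package decision — the transforms are independent and the pipeline must
  fix one).
- kNN imputation (k = 10 default) first removes genes missing in more than
  20% of samples, then replaces each missing cell by the mean over the k
  nearest genes' values at that sample. The neighbour distance is the mean
  squared difference over mutually observed samples — scaling by the number
  of shared samples makes genes with different missingness comparable.
  Observed cells are never altered. Written by hand because the gene-axis
  orientation and this distance rule are specific to this pipeline.
- Per-gene mean-centering (idempotent to 1e-9).
- Quantile normalisation: every column receives the element-wise mean of the
  per-column sorted vectors; within-column ties receive the mean of the
  reference values across their tied ranks (the behaviour of the widely used
  microarray implementation).
- File conventions: UTF-8, tab-delimited (CSV selectable), '.' decimal,
  empty cell or "NA" = missing. Models serialise to JSON with a format
  version, gene list, signs, threshold and training summary; reading
  validates all of these.

## Synthetic data generator

The generator emulates log-scale, mean-centred two-class cohorts:
uninformative genes are Gaussian(0, σ) for all samples; informative genes are
additionally shifted by ±(effect size)·σ in class 1, with a configurable
fraction down-regulated. Optional equicorrelation ρ within the informative
block is produced by a single shared latent factor entering each gene with
its own direction, so sign-corrected informative genes are positively
equicorrelated — the simplest structure under which metagene averaging beats
single genes, mimicking co-regulation. Defaults (2000 genes, 50 informative,
1.5 SD effect, 30 vs 30 samples, σ = 1, ρ = 0, half the informative genes
down-regulated) describe a moderately hard cohort in which the planted genes
are individually informative (expected oriented AUC ≈ Φ(1.5/√2) ≈ 0.86) yet
scattered among a large null background.

The paired train/validation draw shares the planted structure between two
independent cohorts and adds per-gene offsets ~ Gaussian(0, batch shift) to
the validation cohort, mimicking cross-platform location shift. What the
generator does **not** emulate: count-based (RNA-seq) noise, probe effects,
heteroscedastic genes, outlier samples, or correlation among uninformative
genes. Tests passing on this generator therefore demonstrate protocol
correctness (no leakage, correct arithmetic, qualitative robustness), not
clinical-grade performance on real cohorts.

## Problem sizes used in the checks

The behavioural suite runs at desk scale, chosen once as the smallest sizes
at which each claim is statistically clear: null envelope from 10,000 genes
× 56 samples; leakage guard on 200 genes × 40 samples, 100 replicates,
signature size 50; signal recovery at the generator defaults over 10 seeds;
transfer robustness at batch shift 0.5 over 3 seeds; the signature-size
sweep (5–300 in steps of 5) on 1000 genes with 100 informative at 0.8 SD and
ρ = 0.3 over 10 seeds — a deliberately non-saturating regime in which small
signatures are sensitive to composition, so the stabilisation of larger
signatures is visible rather than masked by ceiling accuracy.

## Known limitations

- The threshold tie-break (sensitivity, then larger threshold) and the
  lexicographic ranking tie-break are package conventions; other
  implementations may differ on exactly tied inputs.
- Balanced accuracy is undefined when a class is absent from the truth; such
  calls raise rather than return a degenerate value.
- LOOCV is the only cross-validation scheme offered (no k-fold or
  Monte-Carlo variants), matching the evaluation protocol the method was
  designed around.
- AUC confidence intervals, smoothed ROC curves, probabilistic outputs and
  multi-class extensions are out of scope.
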