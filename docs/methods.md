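# Methods

This note documents the models, procedures and numerical choices behind
grnkit, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

Given a gene-by-sample expression compendium and a set of experimentally
validated transcription-factor (TF) → target regulatory pairs, we cast
gene-regulatory-network (GRN) inference as supervised binary
classification of TF–target pairs. A candidate pair is featurized as the
TF's expression vector concatenated with the target's expression vector
across all S compendium samples (2S features). Positives are curated
pairs (or pairs transferred from a reference species through homolog
maps); negatives are sampled uniformly from the admissible TF × genome
cross product, excluding known positives and self-pairs. Trained
classifiers then score all TF × pathway-gene pairs, and TFs are
prioritized by how often they appear among the top-k highest-scoring
pairs.

## TMM normalization

Raw-count compendia are normalized with the weighted trimmed mean of
M-values. For sample k against reference r (the sample whose upper
quartile of library-size-scaled nonzero counts is closest to the mean
upper quartile):

- genes with a zero count in either sample are excluded;
- M_g = log2[(y_gk/N_k)/(y_gr/N_r)], A_g = ½·log2[(y_gk/N_k)(y_gr/N_r)];
- the top and bottom `logratio_trim` (default 0.30) of M and
  `abs_expr_trim` (default 0.05) of A are trimmed by rank, with ties in
  the trim ranks broken by a stable sort so results are reproducible;
- the factor is 2 to the precision-weighted mean of the surviving M, with
  inverse delta-method variance weights
  w_g = 1/[(N_k−y_gk)/(N_k·y_gk) + (N_r−y_gr)/(N_r·y_gr)];
- factors are rescaled to geometric mean 1 (enforced to 1e-9).

The normalized matrix is counts divided by the effective library size
(library size × factor) and multiplied by the mean library size, keeping
values on a counts-like scale. The implementation agrees with a
brute-force enumeration oracle to below 1e-9 and with the Bioconductor
implementation (same reference column) to ~1e-10 on zero-free fixtures;
with zeros present, tie handling at trim boundaries may differ in the
last kept gene.

## Neural models

The neural stack is implemented directly in NumPy (analytic
backpropagation, verified against numeric differentiation to ~1e-7).

**FCN.** dense(256, ReLU) → dropout → dense(128, ReLU) → dropout →
sigmoid(1).

**CNN.** The 2S pair row is reshaped to a 2 × S grid — TF expression in
row 0, target expression in row 1 — so that 3 × 3 kernels mix the two
genes locally along the sample axis. Architecture: conv(k1, 3×3, ReLU,
"same" padding) → maxpool(1, 2) → conv(k2, 3×3, ReLU, "same") →
maxpool(1, 2) → flatten → the same dense head. Pooling only along the
sample axis preserves the two-row TF/target structure through both conv
blocks. The flatten width is 2 · ⌊⌊S/2⌋/2⌋ · k2, checked in tests against
an independent shape trace. The 2 × S reshape and the (1, 2) pooling are
this package's design; 1-D pair vectors admit 3 × 3 kernels only after
some such choice, and this one is the minimal structure-preserving
option.

**Training.** Mini-batch RMSprop (rho 0.9, epsilon 1e-7), defaults:
learning rate 3e-5, batch size 100, 100 epochs, dropout 0.2 after each
dense layer, Glorot-uniform initialization seeded from the model config.
Eight loss functions are supported — binary cross-entropy, hinge (labels
mapped to ±1), MSE, MSLE, MAE, Poisson, Huber (delta 1.0) and LogCosh —
each validated against its textbook closed form on a toy vector. Poisson
and MSLE are unconventional for sigmoid outputs against 0/1 targets; a
warning is logged, and they are supported because the benchmark sweeps
them regardless. Reproducibility is bitwise for a fixed seed on a single
device/thread configuration; across platforms only statistical equality
should be expected.

Expression inputs to neural training are log1p-transformed and
per-column standardized (`preprocess_features`); training-set statistics
are reused for test data. Classical classifiers consume either raw
features ("plain") or encoder features ("hybrid") without further
scaling.

**Hybrid models.** After the CNN trains end-to-end with BCE, its
conv/pool/flatten prefix becomes a fixed feature extractor (inference
mode, dropout off, deterministic); the flattened activations train one of
nine scikit-learn classifier families (logistic regression, SVM, decision
tree, k-NN, random forest, extremely randomized trees, AdaBoost, gradient
boosting, bagging). SVM scores come from the decision function squashed
through a logistic map — monotone, so rankings and AUC are unaffected.

## Transfer learning

A CNN trained on a data-rich source species donates its convolutional
kernels to a target-species model. Kernels are width-agnostic, so they
transfer even when sample counts differ between species; the dense head
is rebuilt for the new flatten width and freshly initialized. Three modes
are compared on one shared target test set: `scratch` (random
initialization, the no-transfer baseline), `frozen` (transferred kernels
fixed, only the head trains) and `fine_tune` (everything trains). The
small-data harness draws, per class, 100 training and 500 test pairs,
disjointly, from the target pool; the epoch budget for target training
defaults to 100, matching source training.

## Performance metrics

Accuracy, precision, recall, specificity and F1 are computed from
confusion counts at threshold 0.5 (configurable); ratios with zero
denominators are reported as `None` with a warning, never coerced to 0.
The ROC curve sweeps thresholds over unique scores; tied scores collapse
into single curve points so the trapezoidal area equals the Mann–Whitney
concordance probability with half credit for ties (verified exactly
against a pairwise-enumeration oracle and against scikit-learn).
Cross-validation is stratified k-fold (default 10), seeded.

## Ranking

Scored pairs are sorted by score descending with deterministic
lexicographic tie-breaking (tf_id, then target_id); the top k (default
1000) are kept and each TF's frequency among them is its priority.
Frequencies are conserved (they sum to min(k, #pairs)) and bounded by the
pathway size. The Spearman baseline scores each pair by |ρ| between the
two expression vectors (average-rank ties; each gene is ranked once, so
large cross-pair tables are cheap); constant expression vectors yield an
undefined score, flagged and excluded from ranking with a warning.

## Synthetic data generator

The generator emulates the premise that regulated targets co-express
with their TFs while unrelated genes are independent. Latent expression
is Gaussian: baseline genes are iid N(0, 1) across samples; a regulated
target follows

    target = ( f(β'·TF) − E[f] + ε ) / sqrt(Var[f] + σ²),  ε ~ N(0, σ²)

where f is the configured nonlinearity (identity, square, or positive
indicator), β' is the nominal coupling β jittered ±50% per pair with a
random sign (activation/repression), and the analytic standardization
makes the target's marginal match unregulated genes — so at β = 0 the
positives are exactly distributed like negatives, giving a clean null for
leakage controls, while the dependence structure carries the signal.
Each target gene has at most one regulator (so the generative law above
is well-defined), and an optional planted master regulator can own the
first n couplings, giving a synthetic pathway with a known top TF.

Observed expression is exp(latent) — log-normal, like normalized RNA-seq
abundance, and non-negative as the compendium container requires. In
count mode the latent passes through an exponential link into
gamma-Poisson (negative binomial, dispersion 0.1) counts with
sample-specific depths spanning exactly a 5-fold range, specifically to
exercise TMM on realistic library-size spreads.

The two-species generator re-expresses the same couplings in fresh
samples, emits `fanout` homolog copies per gene with N(0, divergence²)
latent perturbations, and produces the target species' positive labels by
mapping the source positives through the emitted homolog tables — the
same code path users run.

What the generator does not emulate: transcriptome-wide covariance,
batch effects, tissue structure, real pathway topology, or unbalanced
positive sets. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal, not field performance on
real compendia.

## Study problem sizes

The self-contained studies run by the test suite and
`scripts/acceptance.py` use scaled synthetic compendia chosen to keep a
full run on one CPU core comfortable while preserving the studies'
structure:

- hybrid signal recovery: 2,500 genes, 100 TFs, 200 samples, 1,000
  positive + 1,000 sampled negative pairs, 80/20 stratified holdout,
  (8, 8)-kernel CNN encoder trained 30 epochs, random-forest head;
  5 seeds, plus a β = 0 control;
- transfer: 1,500 genes, 60 TFs, 200 samples, 700 positives per species,
  divergence 0.6 (a moderately diverged species pair — far enough that
  200 target training rows are limiting, which is the regime transfer
  learning addresses), source CNN trained 100 epochs at the default
  learning rate, 100 + 100 target training and 500 + 500 test pairs per
  class, 5 seeds;
- ranking: 1,000 genes, 200 candidate TFs, a planted master regulator
  driving a 20-gene pathway, Spearman scoring, top-1000 frequency
  ranking, 5 seeds.

## Known limitations and open choices

- The real studies' compendia and curated pair sets are external
  resources; the package reproduces their construction arithmetic and the
  behavior of the methods on synthetic data, not the published accuracy
  tables, which depend on those datasets.
- Whether downstream models should consume normalized expression on
  linear or log scale is not fixed by the method definition; the package
  defaults to log1p + standardization for neural training (documented
  above) and leaves the compendium itself linear, with
  `ExpressionCompendium.log1p()` available.
- Negative pairs are sampled once with a recorded seed rather than
  re-sampled per run; homolog-mapped pairs are de-duplicated.
- The Spearman baseline uses the same top-k frequency procedure as model
  scorers; other cutoff recipes (e.g. per-pair score thresholds) are
  possible and would change its frequencies.
- The prediction threshold for accuracy-type metrics is 0.5 unless
  configured otherwise.
- Model weights persist as a `.npz` array container plus a JSON sidecar
  holding the configuration, seeds and training history.
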