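# Methods

This note documents the models and procedures implemented in
`lesionselect`, the parameters that matter, the synthetic data the test
suite relies on, and the numerical and design choices made where the
problem left them open.

## Pipeline overview

The package implements the feature-level stages of a lesion-classification
pipeline: serial fusion of per-extractor feature blocks, feature-subset
selection by an entropy-controlled gray wolf optimizer (ECGWO), and
hold-out classification with a standard binary metric panel. Image-level
feature extraction is a declared plug-in boundary: any samples × features
matrices (CSV or Parquet) can be supplied, and the shipped synthetic
generator stands in for CNN-derived features during testing.

## Serial fusion

Fusion is ordered column concatenation with provenance: blocks of widths
p and q produce a fused matrix of width p+q, and `column_origin` records
(block, within-block index) per fused column, so the concatenation is
invertible (`FusedFeatures.project`). No rescaling is applied at fusion
time; selection and classification see raw values. The five benchmark
combinations (FV2–FV3, FV3–FV4, FV2–FV4, FV2–FV3–FV4, FV1–FV2–FV3–FV4)
are provided as a convenience over blocks named FV1..FV4, whose reference
widths are 2, 1536, 1026 and 1920.

Reduction percentage is `round_half_away_from_zero(100·(1 − d_out/d_in))`,
capped at 99 because at least one column always survives selection. The
half-away-from-zero rule reproduces 14 of the 15 published per-dataset
reduction rows from their own printed dimensions; the remaining row (PH2,
all four blocks: arithmetic gives 86, printed 88) is asserted in the test
suite as a documented inconsistency of the printed table rather than
silently matched.

## Gray wolf optimizer

The canonical continuous GWO: pack positions initialized uniformly within
bounds from a seeded generator; per-dimension coefficients A = 2a·r1 − a
and C = 2·r2 with r1, r2 ~ U[0,1] drawn fresh per dimension, per leader,
per wolf, per iteration; control scalar a decaying linearly from 2 to 0
over the configured iterations; each wolf moving to the mean of the three
leader-guided points x_k = leader_k − A_k·|C_k·leader_k − x|, clamped to
bounds; leaders (α, β, δ) replaced only by strict improvements, making the
best-so-far trace monotone. Runs are bit-reproducible per seed.

Some printed descriptions of the update rule wrap the displacement in
nested absolute values, x_k = |leader − |A·D||, which confines the search
to non-negative coordinates and breaks optimization on signed domains; the
canonical signed form is the default here and the nested-absolute variant
is available behind `literal_update=True` for comparison. Engineering
sanity targets (not external claims): median final fitness < 1e−2 on the
5-D sphere with 30 wolves × 300 iterations over 10 seeds, and 2-D
Rastrigin < 1.0 in at least 8/10 seeds; the implementation comfortably
exceeds both.

## Entropy-controlled selection

Wolves occupy [0,1]^d; a position decodes to a mask by thresholding at 0.5,
with repair (largest component, ties to the lowest index) guaranteeing a
non-empty subset.

The information term needed a concrete reading of "entropy of the selected
vector", and several were possible (per-sample flattening, histogram
entropy per feature, energy-based). The implemented choice: per-selected
column energy e_j = mean_i |x_ij|, normalized to a probability vector
η = e/Σe over the selected subset (uniform fallback when Σe = 0), scored by
Shannon entropy H(η) = −Σ η log2 η. This yields a proper distribution over
exactly the selected features, is scale-aware, and costs O(k) per candidate
once column energies are precomputed.

Raw entropy grows like log2 k and would reward selecting everything, which
contradicts the substantial reductions this kind of selector is meant to
deliver. The fitness therefore normalizes the entropy and adds an explicit
sparsity term:

    fitness(mask) = H(η)/log2(max(k, 2)) − λ·k/d,

maximized; λ defaults to 0.5 and λ = 0 recovers the bare objective (with
no reduction pressure — documented, not asserted). With λ = 0.5 the
optimum is a very small near-uniform subset, and on the default synthetic
layout (448 columns) the selector reliably cuts > 99 % of columns; the
selection-pressure test asserts the weaker property median reduction ≥ 50 %
over seeds 1–5.

### Hybrid (wrapper) mode

Hybrid fitness blends inner-validation accuracy of a contract classifier
(default: 1-NN with Euclidean distance) with the entropy objective:
w·accuracy + (1−w)·entropy_fitness, w = 0.9. The accuracy term is averaged
over 3 stratified fit/validation splits (validation fraction 0.2), all
derived deterministically from the run seed. A single small split proved
exploitable: with ~3000 candidate evaluations against one 40-sample
validation set the optimizer finds masks that are perfect on that set but
~5 points worse on fresh splits, which measurably degraded downstream
accuracy; averaging over a few splits is the standard wrapper remedy and
restores the non-degradation property while preserving seeded determinism.
Entropy mode never sees labels (a pure filter); hybrid mode requires them.

### Known limitation: recovery saturation

On the recovery layout (500 columns, 20 informative at effect size δ = 2),
the wrapper objective does **not** retain the full informative set, and
cannot be expected to: with class means δ = 2 within-class SDs apart per
informative column, the Bayes error of a k-column subset is ≈ Φ(−√k),
already ~1.3e−3 at k = 9 — far below what a ~40-sample validation split
(resolution 1/40) or even a few repeated splits can distinguish. Once a
dozen informative columns are kept, adding the rest is invisible to the
accuracy term, and the sparsity term actively removes them. Measured
informative-column recall over seeds 1–5 is 0.20–0.30, while the
selected-condition mean accuracy stays within ~2 points of training on all
500 columns. The corresponding recall assertion in the acceptance tests is
intentionally left as a failing check rather than weakened: it documents a
real property of wrapper selection at this effect size — subset-accuracy
optimization identifies a *sufficient* informative subset, not the
*complete* one.

## Evaluation harness

Splitting is a single stratified hold-out per seed: per class,
round(train_fraction·n_c) rows go to training (clamped so both sides keep
at least one sample), with the 70:30 default. Confusion counts are taken
against the declared positive class (default: the second class, playing
"malignant"), and the panel — accuracy, sensitivity, specificity, FNR,
FPR, F1 — satisfies the complement identities exactly by construction.
Zero-denominator ratios are reported as NaN with a warning, never as 0.

Classifier specs map to scikit-learn estimators: linear/quadratic/cubic
SVM (SVC with linear or polynomial kernels, library defaults otherwise);
fine/medium/weighted KNN (k = 1; k = 10; k = 10 with squared-inverse
distance weights); subspace-KNN (bagged 1-NN over random half-subspaces,
30 learners); AdaBoosted trees (30 learners, ≤ 20 splits). RUSBoost has no
implementation in the dependency stack, so a minimal seeded SAMME-style
booster with per-round class-balanced random undersampling is included.
Exact internal defaults of the original GUI-based implementations (box
constraints, subspace dimensions) are not reproducible and are left at the
adapter library's defaults.

`compare_conditions` evaluates each classifier with and without the
selected subset per seed. When given a selector configuration it learns a
label-aware mask per seed *on training rows only*; a canary test verifies
that shuffling test-row labels changes neither the learned mask nor the
test-set predictions.

## Synthetic data generator

The generator emulates the *shape* of fused deep-feature data, not CNN
activation statistics: several named blocks of very different widths and a
skewed two-class cohort (defaults: 200 samples at 0.8/0.2 mirroring the
160/40 benign/melanoma composition of the PH2 collection; block widths
2/154/102/190, the benchmark extractor widths scaled ×0.1 to keep
full-pipeline tests fast). Informative columns are class-conditional
Gaussians with means ±δ/2 (δ = 2 by default) and unit SD; redundant
columns are unit-variance random linear combinations of 1–3 informative
parents plus N(0, 0.1²) noise (correlating with their generating
combination at |r| ≳ 0.99); noise columns are standard normal. Default
informative/redundant counts are (0, 8, 5, 7) per block — 20 of each,
spread over the three wide blocks and placed at seeded random positions.
The whole draw is a pure function of the generating
specification object (seed included).

`oracle_separability` scores a prior-weighted nearest-centroid rule
(argmax_c −‖x − μ_c‖²/2 + log π_c, the Bayes rule for the generating
model) on the informative columns over a fresh 70:30 split — an upper
reference for recovery tests that approaches the majority-class proportion
as δ → 0.

What passing tests on this generator do **not** show: real deep features
are rectified, sparse, heavily correlated across extractors and far from
Gaussian, and real benign/malignant signal is not confined to a known
column subset. The generator validates code paths, determinism, accounting
and recovery behaviour, not clinical performance.

## Problem sizes and budgets

Default test and acceptance problem sizes were chosen to keep a full run
on one CPU in a few minutes: GWO benchmarks at 30 wolves × 300 iterations,
selection at 30 wolves × 100 iterations over 448–500 columns, five seeds
per stochastic property. The published full-width matrices (up to
271 × 4484) are exercised only through the dimension-accounting tests,
which are O(width) and instant.

## Other numerical choices

- All feature values are processed in float64; CSV I/O uses round-trip
  float parsing so read∘write is exact at stored precision.
- Masks serialize as a 0/1 character line plus a JSON sidecar (selected
  count, optional column-origin map) — bit-exact and human-checkable.
- The columnar binary format is Parquet.
- Out-of-bounds optimizer positions are clamped to bounds after each
  update; objective non-finiteness raises immediately, naming the wolf.
- Pipeline manifests hash every artifact (SHA-256) and the configuration
  (excluding the output directory), making reruns verifiable byte for
  byte; manifests contain no timestamps.
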