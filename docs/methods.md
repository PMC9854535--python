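# Methods

This note documents the models and procedures implemented in `mitoboost`,
the defaults chosen where the design was genuinely open, and what the
synthetic data does and does not establish about real histopathology.

## Artificial hummingbird algorithm (`ahba`)

The optimizer minimizes f over a box [Low, Up] ⊂ R^d with n food sources.
Initialization draws each coordinate as Low + r(Up − Low), r ~ U(0,1). An
n×n visit table stores, per (bird, source), the iterations since that bird
last visited that source; the diagonal is null.

Per iteration each bird performs, with probability 0.5 each (decided
per bird, not per iteration), either

* **guided foraging** toward the source with the bird's maximal visit level
  (ties broken by better fitness): v = x_tar + a·D⊙(x_i − x_tar), or
* **territorial foraging** around its own source: v = x_i + b·D⊙x_i,

with a, b ~ N(0,1) and D a binary flight mask: axial (one random
coordinate), omnidirectional (all d), or diagonal (k distinct random
coordinates, k = max(2, ⌈r1(d−2)⌉ + 1), r1 ~ U(0,1); diagonal flight
requires d ≥ 3 and falls back to axial below that). The three flight kinds
are drawn with equal probability 1/3 — the selection rule is not fixed by
the algorithm's usual description, so it is exposed in `AHBAConfig`.

Candidates are clamped coordinate-wise to the box (simplest auditable
out-of-bounds rule; a debug log line fires when clamping occurs) and replace
the bird's source only on *strict* fitness improvement, i.e. ties keep the
old source. Visit bookkeeping: the acting bird's levels toward unvisited
sources grow by one, the visited source resets to zero, and when any
source's position is replaced every other bird's level toward it is set
above that bird's row maximum (it has never seen the new position). Every
2n iterations (the canonical migration period; the literal reading "every
2 iterations" of some descriptions is selectable via `migration_period`),
the worst source is replaced by a fresh uniform draw.

Minimization is the convention throughout; "maximum nectar refilling rate"
corresponds to the minimum objective. Determinism: all randomness flows
through one `numpy` generator seeded from the config.

## Adamax (`adamax`)

State: first moment m, infinity-norm moment u, step counter t. Update:
m ← β₁m + (1−β₁)G; u ← max(β₂u, |G|); w ← w − η/(1−β₁ᵗ)·m/(u+ε). Only m
is bias-corrected (the max-based u needs none). ε (default 1e−8) guards
u = 0 before any non-zero gradient; defaults η = 0.01 (the study's stated
learning rate), β₁ = 0.9, β₂ = 0.999. The first step reduces to
−η·sign(G) as ε → 0, which the tests verify symbolically. The optimizer is
used for toy network stand-ins and as a generic utility; it has no hidden
randomness, so identical inputs give bit-identical trajectories.

## Second-order gradient boosting (`gboost`)

Binary logistic loss (the task is two-class), so g_i = p_i − y_i,
h_i = p_i(1 − p_i) > 0. The regularizer is Ω(f) = γT + ½λΣ_leaves w² — the
standard instantiation consistent with the quadratic per-leaf objective;
the per-leaf minimizer is w* = −G/(H+λ) and the split gain is
½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ.

Numerical choices:

* candidate thresholds at midpoints of consecutive distinct sorted values;
  gain ties broken toward the lower feature index and lower threshold
  (strict `>` during an ordered scan), making trees fully deterministic;
* a split needs gain > 0 and child hessian sums ≥ `min_child_hessian`;
* per-feature sample orderings ("sorted blocks") are computed once from X
  and reused by every round; a per-node re-sorting reference builder is kept
  and tested for node-for-node equality, so the blocks are a pure
  optimization;
* on fully saturated nodes h can underflow to exactly 0; with λ = 0 the leaf
  weight is then defined as 0 (the node exerts no pull);
* the initial margin is the log-odds of the class prior, not a first
  unshrunken tree;
* the hot loops (tree growth and traversal) are numba-compiled; the
  first call in a fresh environment pays a one-time JIT cost.

Defaults: 50 rounds, depth 3, shrinkage 0.1, λ = 1, γ = 0. No row/column
subsampling by default; missing values are rejected rather than routed.

## Hyperparameter tuning (`tuner`)

The tuned space is the standard booster knobs at bounded cost: shrinkage
[0.01, 0.5] on a log scale, rounds [10, 200] and depth [1, 6] as integers
(round half-up), λ [0, 10], γ [0, 5]. The fitness is mean stratified 5-fold
CV misclassification — stratified for stability of the fold class balance
even though the pipeline's outer split is unstratified. Fitness values are
memoized on the decoded parameter tuple (the objective is pure), so
revisits after integer rounding cost nothing; budgets are matched against
baselines in raw objective calls. The default tuning budget is 8 birds × 20
iterations (169 objective calls including initialization and migration),
sized for single-CPU runs.

## Pyramid pooling operators (`ppm`)

Forward-only, with pluggable weights: training a full encoder–decoder
segmentation network is out of scope. Max pooling uses non-overlapping
windows with stride λ = w/o; indivisible sizes are an *error*, never
silently padded — the stride arithmetic presumes exact division and
explicit padding keeps shapes auditable. Bilinear resizing uses the
align-corners convention (endpoints map to endpoints; a singleton dimension
maps to index 0); the convention is stated because dialects differ. The
default pyramid assigns output sizes {1, 2, 6} to max pooling, with the
untouched input map as the fourth branch of the concatenation ({1, 2, 3, 6}
is available by configuration). The attention gate is the minimal additive
form x ⊙ σ(W_x x + W_g g + b). The pipeline's default segmentation backend
is intensity thresholding + connected-component candidate extraction; the
PPM operators are unit-tested against nested-loop and closed-form oracles.

## Descriptors (`features`)

A deterministic handcrafted descriptor behind the feature-extractor
contract: 16-bin min–max-normalized intensity histogram, intensity
mean/variance/skewness, mean gradient magnitude, and foreground area
fraction plus eccentricity of the largest Otsu-thresholded blob (foreground
= darker side, since nuclei are dark on a light background). Deep
embeddings can be substituted through `load_external_embeddings` without
touching the classifier. The histogram components are invariant to constant
intensity rescaling; histogram and moments are invariant to 90° rotations.

## Synthetic data (`synthetic`)

Defaults emulate the study's inputs: 150 patches (75 per class) of 64×64
pixels. Nonmitotic nuclei are single near-round ellipses (eccentricity
0–0.3) at intensity 0.45 on a 0.85 background; mitotic figures are
dumbbells of two elongated lobes (eccentricity 0.75–0.95), darkened by a
chromatin factor 0.55 and speckled, because mitotic figures are
hyperchromatic and irregular. Additive Gaussian noise σ = 0.04. No source
image dimensions or staining details are published for the benchmark, so
these visual parameters are configuration, not constants. Feature tables
are two unit-variance Gaussians separated by `shift` along the first
coordinate (Bayes error Φ(−shift/2)); the reference tables use dim = 5.

The split protocol is unstratified uniform sampling by default because the
study's implied train compositions (44/46 at 60%, 50/55 at 70%) are not the
stratified values; explicit per-class train counts reproduce those
compositions exactly when needed.

**What passing tests show — and don't.** The generators produce idealized,
high-contrast, single-nucleus patches with known ground truth; classifiers
reach near-perfect accuracy on them. Passing demonstrates that every stage
is wired and numerically correct, not that the pipeline reaches any
particular accuracy on real H&E tissue, which has stain variation, touching
nuclei, imposters (apoptotic/hyperchromatic non-mitotic cells) and label
noise that the simulation deliberately omits.

## Metrics (`metrics`)

Per class: recall (reported as that class's balanced accuracy — the Average
row is then the usual balanced accuracy), precision, F = 2PR/(P+R),
G = √(PR), and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
identical for both class views. Rows are kept at full precision; the
Average row is the unweighted mean of the *unrounded* class rows and
half-even rounding to two decimals is applied only at display. Rounding
first can differ: (93.5484 + 100)/2 = 96.7742 → 96.77, while
(93.55 + 100.00)/2 = 96.775 → 96.78. Zero denominators report 0.00 with a
warning.

## Pipeline and problem sizes

The end-to-end run at defaults (150 images, thresholding segmentation,
descriptor features, 70:30 split, 8×20 tuning budget, 5-fold CV) completes
in well under a minute on one CPU; the acceptance script's sizes (10
optimizer seeds, 5 tuning seeds at 169 evaluations each, n = 300 tables)
were chosen as representative desk-scale experiments. Known limitations:
binary classification only, box constraints only in the optimizer, no
approximate split finding for very large tables, and forward-only
segmentation operators.
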