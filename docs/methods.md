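# Methods

## Problem and model

Cyclic multiplexed immunofluorescence (CODEX/PhenoCycler) measures 40+
protein markers per tissue section; routine clinical mIF measures ~7.
`sevenup` predicts the per-cell expression of a large panel from a small
measured one by exploiting two sources of redundancy in tissue:

1. **Co-expression** — many markers covary strongly with a well-chosen
   small panel, so per-cell regression from the measured expressions
   recovers much of the remainder.
2. **Morphology and neighborhood** — cell shape and local context carry
   information that expressions alone do not (an elongated cell in a
   vessel-like neighborhood predicts endothelial markers even when its
   measured expressions are uninformative).

The pipeline is: quantify per-cell expression from images → build
per-cell image patches → train a convolutional cell-type classifier
ensemble whose averaged class probabilities are the *morphology feature*
→ fit one gradient-boosted regressor per unmeasured marker on
[measured expressions ‖ morphology probabilities] → derive cell types
from the completed panel by kNN label transfer with value substitution →
evaluate patchwise.

## Quantification

- **Background correction.** Fluorophore-free "blank" images from the
  first and last acquisition cycle are blended per marker with weight
  w = c/(C−1) for cycle c of C and subtracted (clipped at 0), tracking
  the monotone decay of autofluorescence over cycles.
- **Mask dilation.** Nuclear segmentations are grown for 9 iterations; at
  each synchronous step a background pixel flips to a neighboring cell's
  label with probability (labeled 8-neighbors of that cell)/8.
  Competing labels are resolved by sampling proportionally to neighbor
  counts; cell pixels never revert or overwrite each other.
  Connectivity (8-connected), synchronous updates, and per-label counting
  are design choices; the update rule is verified against an independent
  per-pixel Monte-Carlo simulator (means over 2,000 seeds agree within
  the 99% CI).
- **Normalization.** Per sample and marker,
  `z = zscore(arcsinh(x / (5·q0.2(x))))` with q0.2 the 20th percentile
  (linear interpolation between order statistics) and a population-sd
  z-score. The divisor constant 5 is config-exposed. When q0.2 = 0 the
  divisor falls back to the smallest positive raw value (logged). A
  constant marker raises a degenerate-dispersion error. The q0.2 scaling
  itself is the "quantile" step; no rank-based cross-sample quantile
  mapping is applied. Statistics are per-sample, never pooled;
  inference on new samples recomputes them (a config flag can freeze
  training stats instead).

## Patches

Per cell and measured marker, three 224×224 channels in [0, 1]:
the masked cell rescaled 3× and centered (center-cropped if oversized);
a native-scale 224 px crop at the centroid (≈84.6 µm at 0.3775 µm/px);
and a 448 px crop downsampled ×0.5 (≈169 µm field; the ×0.5 downsample
is an exact 2×2 block average). Geometry is defined purely in
pixels/scale factors; micron figures are reported, not enforced.
Channels are contrast-stretched beforehand with a two-tail percentile
stretch saturating 0.35% of pixels at each tail (an explicit stand-in
for interactive auto-contrast; the fraction is config-exposed).
Context crops retain other cells' pixels deliberately — neighborhood
information is the point. Out-of-bounds regions are zero-padded.

## Featurizer

An ensemble of five identically configured classifiers with different
random initializations is trained to predict cell types from the patch
tensors; the morphology feature is the ensemble-mean softmax vector
(probabilities outperform penultimate-layer embeddings as features).
Training uses cross-entropy with Adam, class-weighted validation F1
evaluated periodically, learning-rate decay ×0.2 on a plateau, stop on a
longer plateau, and best-checkpoint selection. At production scale the
protocol is LR 1e-4 with 5,000-step/75,000-step plateau windows on a
50-layer pretrained residual backbone; those are the config defaults'
reference points. The shipped backbone is a small 3-block CNN on
area-pooled inputs (default 32×32) with a global-average-pooled head and
per-channel input standardization computed on the training set. The GAP
head makes the classifier translation-invariant, so neighborhood signals
are detected wherever they sit in the context crop instead of being
memorized by absolute position — essential for transfer across
coverslips, where niche layouts differ. The trainer is a small
hand-written numpy layer kit (`_nn.py`: shifted-GEMM 3×3 convolutions,
hand-derived backprop, Adam), fully deterministic given seeds; member m
uses seed `base + m`. Benchmark configs train 2 members at
learning rate 1e-2 for ≤1,400 steps — the small-backbone, small-data
operating point; the ensemble-of-five default is unchanged.

## Panel selection

The concrete selector trains P relaxed one-hot selector units
(temperature annealed geometrically 10 → 0.01 over 300 epochs) with a
64-64 MLP decoder under MSE on normalized expressions; at the end each
unit's argmax is a selected marker. Duplicate argmaxes trigger
re-annealing with fresh seeds (≤5 restarts), then greedy fill; total
failure falls back to greedy with a warning. The greedy baseline adds,
at each step, the marker minimizing the reconstruction MSE of a ridge
decoder. Both methods report their final MSE from a ridge decoder refit
on the hard subset so that concrete, greedy, and exhaustive search are
compared on one scale. Selection runs on expressions only.

## Imputation

One XGBoost regressor per unmeasured marker (squared error, learning
rate 0.1, 500 estimators, depth 3, column subsampling 0.7, single
thread, fixed seed) on the shared feature matrix. "Joint" prediction
decomposes into independent per-target fits under squared error. No
early stopping (fixed 500 rounds). Splits are grouped by coverslip —
the acquisition unit — so evaluation always happens on coverslips unseen
during any fit; the expression-only model (features = none) is the
morphology ablation.

## Cell typing

Ground truth: PCA (top 20 PCs) of the normalized full panel → kNN graph
(k = 30, Euclidean, union-symmetrized) → Leiden modularity communities
(resolution 1.0, seeded) on a reference of up to 10,000 cells →
cluster-level annotation (programmatic majority vote against generative
truth on synthetic data, standing in for expert annotation) → a
majority-vote kNN classifier (k = 30, matching the graph k; ties break
toward the class more frequent in the reference) transfers labels.
Predicted types substitute the imputed values for the unmeasured markers
in the full-width vector and reuse the stored PCA basis and reference —
so feeding the true values through the substitution path reproduces the
ground-truth labels exactly (a no-regression guarantee that is tested).
PCs are not variance-scaled before graph construction.

## Metrics

Patchwise PCC correlates patch-mean measured vs. predicted expressions
over a regular grid (default 128 px, config-exposed, always reported);
zero-variance patch means raise rather than propagate NaN. Patchwise F1
calls a patch positive for a type if ≥1 cell of the type is present;
the weighted mean uses true-positive-patch counts as weights. The
adjacency matrix counts unordered spatially adjacent type pairs on a
k = 5 symmetrized kNN spatial graph (Delaunay-free choice,
config-exposed), normalized to grand sum 1 and compared by elementwise
RMSD. A patch-size sweep utility and a percentile bootstrap over
patches (a convention choice, flagged as such) are provided for
reporting only.

## Synthetic tissue

The generator emulates exactly what the downstream stages consume:
non-overlapping rasterized equal-area ellipses (disk / eccentric /
large-disk families) placed by dart-throwing with a Pólya-urn
aggregation of niche groups (a new cell joins a uniformly chosen
existing group member with probability `niche_strength`);
type-conditional expression means with within-type Gaussian sd;
optional linear mixing making unmeasured markers functions of measured
ones; a shape marker that is a pure function of eccentricity (Bayes PCC
0 for expression-only prediction, by construction); additive
per-coverslip intensity shifts; additive per-cell noise clipped at 0.
Intensity is constant within a cell, so noiseless samples quantify back
to their generating means exactly. Same recipe + seed is bit-identical.

Two canonical study conditions:

- **Co-expression benchmark** (`default_recipe`): three coverslips ×
  700 cells, four types (T-cell/tumor/stromal/macrophage-like) over an
  8-marker panel whose four unmeasured markers are noisy linear
  combinations of the measured four; within-type sd 0.5, cell noise 0.2,
  moderate niching. The end-to-end run must recover patchwise weighted
  F1 ≥ 0.8 against the generative truth and be bit-reproducible.
- **Ablation tissue** (`ablation_recipe`): three coverslips × 450 cells.
  Three focal types share identical measured means: an elongated type
  (present in both niche flavors, so context carries no information
  about it) drives `TSHAPE` = f(eccentricity); two round types differ
  only by which bright "beacon" type they co-locate with, driving
  `TNICHE_A`/`TNICHE_B`. Expression-only imputation of all three targets
  is near-uninformative; cell-only patches recover `TSHAPE` but not the
  niche targets; full patches recover all three. This makes the
  morphology and context ablation directions strict by construction.

What the generator does **not** emulate: point-spread/optical blur,
shot noise, segmentation errors, touching cells, within-cell intensity
gradients, spatial marker gradients, or non-additive batch effects.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and the direction of its morphology/context advantages under
idealized imaging, not performance on real CODEX cohorts.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation between order statistics everywhere.
- PCA: deterministic SVD with a fixed sign convention (largest absolute
  loading positive).
- kNN: Euclidean, self-neighbors dropped, union symmetrization.
- Dilation label ties: proportional sampling (a tie cannot survive
  sampling; the documented fallback is lowest label id).
- Zero-variance marker → error; q0.2 = 0 → smallest-positive fallback;
  empty mask → error; zero-row imputation → empty output with full
  schema; constant image in contrast stretch → zeros with a notice.
- All randomness flows from `numpy.random.default_rng` with explicit
  seeds; stage seeds are fixed offsets from one master seed; XGBoost
  runs single-threaded with a fixed seed, so full runs are
  bit-reproducible.

## Problem sizes

Unit tests run on tens-to-hundreds of cells. The acceptance
computations use: 2,000-seed Monte-Carlo dilation on 21×21; a
2,000-cell 12-marker panel with exhaustive C(12,7) search; 16,000 cells
for the attenuation check; 3 × 450 cells for the ablation runs; and
3 × 700 cells for the end-to-end benchmark — sizes at which every
result above is stable under reasonable seed changes on a single CPU.

## Known limitations

- The production-scale pretrained residual backbone is not shipped; the
  small CNN is the only backbone, and morphology features on real
  tissue would need the larger model.
- Normalization inference defaults to per-sample recomputation; frozen
  training statistics are available but secondary.
- The concrete selector's schedule (decoder width, epochs, annealing)
  follows common practice for concrete feature selection and is
  config-exposed rather than tuned.
- Bootstrap confidence intervals resample patches; other resampling
  units (cells, samples) are not implemented.
- The UMAP concordance view is out of scope; no projection hook is
  tested.
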