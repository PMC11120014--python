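# Methods

This note documents the models, numerical choices and known limitations of
`radtexnet`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Texture model

Every voxel gets a gray-level co-occurrence matrix (GLCM) built from all
voxel pairs inside the centered cubic window (default edge 3) whose
difference vector equals a fixed offset; pairs are counted in both
orderings, so the GLCM is symmetric and, after normalization, a probability
distribution over gray-level pairs. The 13 offsets are the unique 3D
directions at Chebyshev distance 1 (one of each ± pair). Features are
computed per offset and averaged across offsets, which removes direction
dependence and yields one map per feature.

**Quantization.** Intensities are binned into `G` equal-width levels
(default 32 library-wide; 8 at desk scale, where windows contain only 27
voxels and finer bins would leave most GLCM cells empty). The bin of `x`
over range `(lo, hi)` is `floor(G (x − lo)/(hi − lo))` with `x = hi` mapped
to `G − 1`; values outside a fixed range are clipped. Quantization is
computed once per volume (over the volume range, or over the lung window
when `quant_range` is set — the default in the pipeline, so maps are
comparable across volumes). Per-window quantization is not offered as the
per-volume choice is both faster and deterministic under cropping.

**Feature formulas** (with `p(i,j)` the normalized symmetric GLCM, marginal
`p_x`, marginal mean `μ` and variance `σ²`):

- Energy `Σ p²`, Entropy `−Σ p log₂ p` (with `0·log 0 := 0`),
  Inertia `Σ (i−j)² p`, Inverse difference moment `Σ p/(1+(i−j)²)`,
- Correlation `Σ (i−μ)(j−μ) p / σ²`,
- Cluster shade `Σ ((i−μ)+(j−μ))³ p`, cluster prominence the same with
  fourth power,
- Haralick correlation `(Σ i·j·p − μ_t²)/σ_t²` with `μ_t, σ_t²` the mean
  and variance of the marginal distribution.

**A structural identity worth knowing:** on a *symmetric* GLCM the two
marginals coincide with each other and with the per-index distribution, so
Correlation and HaralickCorrelation are algebraically the same number
(expand `Σ(i−μ)(j−μ)p = Σ ij p − μ²`). Both are computed (through different
code paths, joint central moments versus marginal raw moments) and coincide
to rounding error. Downstream feature selection therefore sees two
identical columns for one statistic; a random forest splits that statistic's
importance between them arbitrarily, so which of the two *names* ranks
first is effectively a coin flip even when the statistic itself dominates.
This is a property of the formulas, not a bug, and it is why selection
outcomes should be read at the level of the correlation family.

**Degenerate windows.** Constant windows (air, padded background) have zero
marginal variance; both correlation features return 0 there rather than
NaN. Border voxels use replicate padding so maps are full-size.

**Implementation.** The whole-volume path never materializes per-voxel
GLCMs. For each offset it loops over the gray-level pairs present in the
volume; the windowed pair count for one pair is a box correlation of the
pair-indicator field with an offset-trimmed kernel (`scipy.ndimage`), and
all eight features are assembled from eleven running moment fields. The
test suite checks every voxel of every feature against a naive per-window,
per-offset double-loop oracle to 1e-8 (measured agreement is ~1e-12).

## Feature selection

Patches are non-overlapping cubes (published scale 16³; 8³ at desk scale so
a 32³ volume still yields 32 patches); trailing voxels that do not fill a
patch are discarded. Folds split at *volume* level (stratified by label) so
patches of one volume never appear on both sides — patch-level splitting
would leak, but is available behind `by_volume=False` for fidelity
experiments. Per fold a `RandomForestClassifier` (100 trees, library
defaults otherwise, seeded) supplies mean-decrease-in-Gini importances
averaged over trees; the map score is the sum of its mean-column and
std-column importances averaged across folds, and the argmax is selected.

## Networks

All layers are numpy modules with hand-written backprop (`nn.py`); the test
suite verifies end-to-end gradients against central finite differences at
~1e-9 relative. Default dtype is float64; the full-scale forward pass uses
float32 and a depth-chunked im2col to bound memory.

- **CNN branch**: 7 blocks of conv → ReLU → batch-norm. The stated block
  count (7) with six filter widths is resolved by giving the stride-1 stem
  the first width, i.e. widths 16 | 16, 32, 64, 128, 256, 512; six stride-2
  kernel-4 pad-1 blocks halve 256×256×64 to 4×4×1. Global average pooling
  and one FC layer produce the 768-vector. The conv → ReLU → BN order is
  kept as published even though conv → BN → ReLU is more common
  (`bn_before_act` swaps it).
- **ViT branch**: non-overlapping 16³ patch embedding (a linear map on
  flattened patches), a learned classification token and learned per-index
  position embeddings (the paper-scale anisotropic input gives a 16×16×4
  token grid, 1025 tokens with the class token), then 12 pre-norm
  transformer blocks (6-head self-attention, MLP ratio 4, exact GELU); the
  final layer-norm'd class-token embedding is the branch output, and every
  block retains its attention tensor for explanation.
- **Fusion**: feature vectors are concatenated (1536-wide at full scale)
  into one FC + sigmoid head; `cnn_only` / `vit_only` modes realize the
  single-branch ablation variants.

Weight init is He-style normal scaled by fan-in, fully seeded.
Average pooling is global; the alternative (strided pooling) is not
implemented since the downstream FC expects a vector.

## Training and evaluation

Binary cross-entropy on the sigmoid output, AdamW (decoupled weight decay
0.01 applied to weight matrices only). Full-scale defaults follow the
published recipe (lr 1e-5, 50 epochs, batch 2, augmentation on). The
desk-scale recipe (`desk_scale_train_spec`: lr 1e-3, 12 epochs, batch 8,
augmentation off) is the package's own choice for 32×32×16 phantoms, where
the higher learning rate converges in minutes and augmentation is
unnecessary for the separability being tested. Augmentation applies random
flips, Gaussian noise (sd drawn from (0, 0.05) on normalized intensities)
and a random in-plane rotation (±10°) with isotropic scale (0.9–1.1);
spatial transforms share one map across channels so CT and texture stay
co-registered. Every resolved parameter is serialized into the run config.

Cross-validation is stratified at volume level with a fixed seed; a fresh
model is trained per fold (fold seeds derived from the spec seed).
Confusion matrices use threshold 0.5; positive class = diffuse disease
(label 1). Sensitivity, specificity, precision, accuracy and F1 follow the
standard count formulas; zero-denominator metrics are reported as NaN.
"Combined AUC" is the trapezoidal AUC of the single ROC over out-of-fold
scores pooled across folds (the per-fold AUCs are also reported); the suite
checks it equals the normalized Mann–Whitney statistic to 1e-10. Both
per-fold mean ± sd metrics and pooled-count metrics are emitted, since the
two conventions differ.

## Explanations

HiResCAM backpropagates the raw class score (the logit for class 1, its
negation for class 0) to a chosen convolution block and sums the
element-wise gradient–activation product over channels. No ReLU is applied
to the raw map; display normalization is min–max per volume. The default
target is the last block; for *localization* use an early block — at full
scale the last block is 4×4×1 and cannot resolve a nodule, and the
localization test accordingly reads the full-resolution stem block.

Attention Rollout multiplies identity-augmented attention matrices across
layers. The recursion as usually printed omits re-normalization; by default
each `(A + I)` is row-renormalized so the rollout stays row-stochastic
(the raw product is available with `normalize=False`). Heads are averaged
before augmentation, and the saliency is the class-token row over patch
tokens reshaped to the patch grid.

## Synthetic phantoms

The generator's job is statistical, not anatomical: two classes that differ
in local co-occurrence structure inside lung-window HU ranges.

- `diffuse_texture` (label 1): white noise smoothed at a correlation length
  (default 1.2 voxels), scaled to amplitude 150 HU (jittered ×0.7–1.3 per
  volume) on a −800 HU background plus 25 HU white noise.
- `focal_nodule` (label 0): −800 HU background with white noise plus
  spherical Gaussian-profile inclusions (default 2 nodules, radius 3,
  contrast +500 HU); the voxel mask of the spheres is returned for
  localization tests.

The correlation-contrast cohort (`correlation_contrast_specs`) uses two
diffuse classes differing only in correlation length (1.2 vs 0.3) with a
deliberately wide amplitude jitter (×0.45–1.55): amplitude-sensitive
statistics then vary as much within class as between classes, leaving the
amplitude-invariant correlation coefficient as the designed discriminant.
Phantoms are bit-reproducible from their seed; cohort members get seeds
derived from the master seed and recorded in the manifest.

What the phantoms do **not** model: anatomy, scanner protocols and
reconstruction kernels, intensity inhomogeneity, class overlap, or
realistic lesion morphology. Passing desk-scale tests therefore
demonstrates that the pipeline's machinery is correct and that the
published architecture can exploit co-occurrence contrast — not that any
particular clinical accuracy would be achieved.

## Problem sizes

Desk-scale studies use 32×32×16 volumes, G = 8 gray levels, 8³ patches, a
reduced ensemble (filters 8/16/32, feature dims 64, ViT depth 2, patch 8),
30 volumes per class and 3-fold cross-validation; the selection study uses
6 volumes per class across 10 master seeds. The full-scale configuration is
exercised forward-only. These sizes were chosen so each study completes in
minutes on a single CPU while keeping every statistical check well-posed.

## Known limitations

- Whether the original texture maps were computed on raw or window-clipped
  intensities is unknowable from the description; clipped is the default,
  raw available by passing an explicit `quant_range`.
- The Correlation/HaralickCorrelation identity above means name-level
  selection between those two is arbitrary; selection results are stable
  only at the family level.
- Training at the published full scale (256×256×64, 50 epochs) is out of
  reach for the numpy implementation in reasonable time; the architecture
  is validated by forward passes and desk-scale training.
- No significance testing between ablation variants is implemented.
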