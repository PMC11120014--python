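# radtexnet

Radiomics texture maps and a multichannel 3D CNN–ViT ensemble for
classifying diffuse versus focal lung disease on chest CT — with built-in
explainability, a cross-validated ablation harness, and a synthetic phantom
generator so the entire pipeline is testable on a desk without clinical
data.

## The problem

Pulmonary sarcoidosis is a granulomatous interstitial lung disease whose CT
appearance is diffuse and easily confused with lung malignancy. Classical
radiomics needs a segmented region of interest, which is ill-defined for
diffuse disease; pure CNNs capture local patterns but little global
context, and vision transformers capture global context but train poorly on
small cohorts. This package implements a workflow that avoids regions of
interest entirely:

1. **Preprocess** — center-crop the axial plane, clip to the lung window
   (−1000, 400) HU, resample to a fixed grid (default 256 × 256 × 64).
2. **Texture maps** — per-voxel 3D Haralick features from sliding-window
   gray-level co-occurrence matrices (GLCM). For each voxel a symmetric
   GLCM is accumulated inside the centered 3 × 3 × 3 window for each of the
   13 unique offset directions at distance 1, and eight statistics
   (cluster prominence, cluster shade, correlation, energy = Σp²,
   entropy = −Σp log₂p, Haralick correlation, inertia = Σ(i−j)²p, inverse
   difference moment = Σp/(1+(i−j)²)) are averaged across offsets into one
   full-size map per feature.
3. **Feature selection** — each map volume is divided into cubic patches;
   the patch mean and standard deviation of the 8 maps form a 16-vector per
   patch, each patch inheriting its volume's label. A 100-tree random
   forest per cross-validation fold ranks the 16 columns by mean decrease
   in Gini impurity; the winning texture map becomes the radiomics input
   channel.
4. **Classifier** — a two-channel (CT + texture map) ensemble: a 7-block 3D
   CNN (conv → ReLU → batch-norm; stem kernel 3/stride 1, six downsampling
   blocks kernel 4/stride 2 at widths 16…512, global average pool, FC to a
   768-vector) in parallel with a 3D ViT (16³ patch embedding, class token,
   12 pre-norm transformer blocks, dim 768, 6 heads). The two feature
   vectors are concatenated into a single fully connected sigmoid head;
   training uses binary cross-entropy with AdamW (full-scale defaults:
   lr 1e-5, 50 epochs, random flip/noise/affine augmentation).
5. **Explainability** — HiResCAM for the CNN branch
   (Ã = Σ_f ∂s_m/∂A ⊙ A_f at a chosen convolution block) and Attention
   Rollout for the ViT branch (recursive row-normalized (A_L + I) products
   read out at the class token), both upsampled and overlaid on the CT.
6. **Ablation harness** — five variants from one sweep (CT-ViT, CT-CNN,
   CT-CNNViT, Rad-CNNViT, RadCT-CNNViT) under stratified volume-level
   k-fold cross-validation, reporting per-fold sensitivity/specificity/
   precision/accuracy/F1 and the combined AUC of pooled out-of-fold scores.

The neural layers (3D convolution, batch-norm, multihead attention,
AdamW, …) are implemented in numpy with explicit backpropagation — the
models here are small enough that a dependency-free, bit-reproducible
implementation is the more transparent choice, and every gradient is
verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
import radtexnet as rt

# a labeled synthetic cohort: diffuse-texture (label 1) vs focal-nodule (label 0)
pos, neg = rt.default_class_specs((32, 32, 16), "easy")
volumes, masks, manifest = rt.make_cohort(30, pos, neg, seed=1)
labels = np.array([v.label for v in volumes])

# per-voxel Haralick texture maps on window-clipped intensities
tspec = rt.TextureSpec(gray_levels=8, quant_range=(-1000.0, 400.0))
map_sets = [rt.texture_maps(v, tspec) for v in volumes]

# which texture map should feed the network?
table = rt.cohort_table(map_sets, labels, patch_edge=8)
report = rt.rank_features(table, n_trees=100, k=5, seed=1)
print(report.selected_map)

# two-channel ensemble, 3-fold cross-validation at desk scale
ct = np.stack([rt.minmax_normalize(np.clip(v.voxels, -1000, 400)) for v in volumes])
rad = np.stack([rt.minmax_normalize(m.maps["HaralickCorrelation"]) for m in map_sets])
cfg = rt.EnsembleConfig(input_channels=2, input_shape=(32, 32, 16),
                        cnn_filters=(8, 16, 32), cnn_feature_dim=64,
                        vit_patch_edge=8, vit_depth=2, vit_dim=64, vit_heads=4)
res = rt.cross_validate(rt.variant_inputs(ct, rad, ("ct", "rad")), labels,
                        cfg, rt.desk_scale_train_spec(seed=0, epochs=12), k=3, seed=1)
print(f"pooled accuracy {res.pooled_metrics['accuracy']:.3f}  "
      f"combined AUC {res.combined_auc:.3f}")
```

On this cohort the run prints

```
HaralickCorrelation
pooled accuracy 1.000  combined AUC 1.000
```

meaning the random forest picked a correlation-family texture map (the
Correlation and HaralickCorrelation statistics coincide on symmetric GLCMs —
see `docs/methods.md`), and the reduced two-channel ensemble separates the
easy-regime phantom classes perfectly under 3-fold cross-validation.

The same flow is available from the shell:

```bash
radtexnet synth --n 30 --shape 32,32,16 --seed 1 --out cohort/
radtexnet run --seed 1 --out run_output/      # full pipeline on phantoms
radtexnet texture --in cohort/vol_0000.nii.gz --out-dir maps/ --gray-levels 8
```

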