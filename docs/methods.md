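# Methods

## Problem and approach

Given a fluorescence-microscopy image, we estimate the number of cells
it contains by *counting by regression*: instead of detecting and
enumerating individual cells, the image is first mapped to one or two
high-level imaging phenotypes — a **dot density map** and a **foreground
mask** — and those phenotypes are regressed onto the integer count.

A dot density map places, for every cell, an isotropic Gaussian kernel
of fixed total mass α at the cell center, so that

    count = sum(density_map) / α.

A foreground mask is a binary image, 1 on cell pixels and 0 on
background. Both phenotypes are image-sized, which lets encoder–decoder
(autoencoder) networks learn them as image-to-image regressions.

Four models share three reusable parts:

| model  | structure |
|--------|-----------|
| DRDCNN | U-Net density branch → VGG-style regression tail |
| FRDCNN | convolutional mask autoencoder → same tail |
| ERDCNN | channel-wise concatenation of both decoded branch outputs → tail with 2 input channels |
| DDCNN  | density branch alone; count = sum(predicted map)/α, no tail |

ERDCNN implements *stacking*: the decoded outputs of the two
independently trained branches are joined as a two-channel feature image
and one regression head learns from both.

## Architectures

**Density branch (U-Net).** `unet_depth` contraction levels (default 4,
base 32 filters doubling per level), two 3×3 conv + ReLU layers per
level, 2×2 max-pooling; mirrored expansion levels with nearest-neighbour
upsampling, a 3×3 channel-halving conv, skip concatenation and two more
convs; final 1×1 conv with ReLU so the predicted map is a valid
(non-negative) density. The output bias is initialized at 0.5: starting
the ReLU output in its active regime avoids the collapse in which MSE
against sparse density targets switches every output unit off before any
structure is learned.

**Mask branch.** A plain autoencoder: three conv(3×3)+ReLU+max-pool
encoder stages, three conv(3×3)+upsample decoder stages — six
convolutional layers in total, no skips — with a sigmoid output in
[0, 1]. Weights are initialized orthogonally, except the output conv's
bias, which starts at −2.0 (sigmoid ≈ 0.12, a typical foreground
fraction): without this prior-probability initialization, MSE against
sparse masks first washes the decoder weights out to reach the
background base rate, after which the sigmoid's vanishing gradients
cannot recover any structure.

**Regression tail.** Four VGG-style blocks, each
[batch-norm → 3×3 conv + leaky ReLU (slope 0.3) → dropout 0.6 →
2×2 max-pool], then flatten and two dense layers ending in a single
linear unit. Counts are reported as continuous values (an optional
rounding flag exists for display).

All of this runs on a compact NumPy engine (`ccens._nn`) with
hand-derived backward passes (verified against finite differences in the
test suite), Adam (β₁ 0.9, β₂ 0.999, ε 1e-7), and float32 tensors in
NHWC layout.

## Two-stage freeze/transfer training

*Stage 1 (feature stage).* Each branch is trained as an autoencoder
against its feature label with Adam and MSE loss: the density branch on
the dot-annotated corpus (S1), the mask branch on the mask-annotated
corpus (S2). Full-scale defaults: 192 epochs, batch 16, learning rate
1e-3.

*Stage 2 (regression stage).* Branch weights are frozen — bit-exactly:
neither the weights nor the batch-norm statistics of a frozen component
change — and the tail is trained against the integer counts on the
combined set S1 ∪ S2 (default 1000 epochs). MSE on counts is used; the
ensembled model transfers both saved branch weight sets, freezes them,
and trains only its two-channel tail.

When every branch is frozen the decoded maps are computed once in eval
mode and the tail trains on the cached features; this is mathematically
identical to backpropagating through a frozen branch and much cheaper on
one CPU. A full-graph backward path exists and engages (with a logged
warning) if a branch is deliberately left trainable.

**Batch-norm re-estimation.** Dropout ahead of a max-pool inflates the
activation variance the next block's batch-norm observes during
training, so running statistics accumulated there misrepresent the
dropout-free evaluation regime and systematically attenuate
predictions. After the regression stage we therefore recompute every
batch-norm's running statistics as the plain average of batch statistics
over the training features with dropout disabled. This removes the
inter-block shift (roughly halving test RMSE on the desk benchmark). A
residual attenuation remains on the final block → dense path, which no
batch-norm recalibrates; it is affine, so correlation-based results are
unaffected, but absolute counts from lightly trained desk-scale models
run a little low. This is a property of the specified tail (dropout 0.6
inside every block), not of the engine.

## Synthetic scenes

The generator emulates the statistical structure of the training
corpora, not any particular simulator's pixel statistics. A scene is
drawn as: count *n* from `count_law`; *n* cells with continuous centers
(uniform, or clustered around ⌈n/30⌉ seeds when `cluster_strength` > 0),
radii from `cell_radius_law`, peak intensities from `intensity_law`;
the image is background + per-cell radial Gaussian intensity profiles
(width radius/2), Gaussian optical blur (`blur_sigma`), additive
Gaussian noise (`noise_sd`), clipped to [0, 255].

Annotations: the density map superposes per-cell kernels (σ = 2 px,
mass α = 100 by default — the source corpora's kernel shape is not
documented anywhere, so these are declared package defaults, exposed as
config fields); the mask is the union of rasterized disks. Non-
overlapping layouts are rejection-sampled with a budget of 100·n draws
and keep centers at least (r₁ + r₂ + 1.5) px apart; the 1.5 px margin
guarantees rasterized disks never touch diagonally, so the mask's
connected-component count equals the cell count exactly.

Presets:

| preset | frame | counts | emulates |
|--------|-------|--------|----------|
| `dot`  | 256×256 | Normal(174, 64) truncated below at 1 | dot-annotated corpus (200 scenes) |
| `mask` | 696×520 | uniform 1–100 | mask-annotated corpus (1200 scenes) |
| `real` | 512×512 | Normal(40, 15) truncated, clustered | nuclei-stained organoid images, unlabeled, 164/107/114 per group |

Truncated-normal counts are redrawn (not clipped) so the configured
mean/sd are only mildly distorted.

What the generator does **not** reproduce: real chromatin texture,
illumination fields, photobleaching, 3-D structure, debris, or the exact
generative algorithms behind the published corpora. Passing tests
therefore demonstrate that the training procedure and architectures
work as specified on data with this annotation structure — not
field performance on real microscopy.

## Preprocessing

Corpora of different shapes are harmonized to one target (default
256×256): RGB is collapsed with the Rec. 601 luma weights
(0.299, 0.587, 0.114); images and density maps are resized bilinearly,
masks with nearest-neighbour (preserving binarity); non-square frames
are stretched (no padding — the 696×520 → 256×256 step implies aspect
distortion is accepted); density maps are multiplied by
(mass before)/(mass after) after resizing so count = mass/α stays
exact; intensities are rescaled to [0, 1]. Count labels are never
altered.

## Evaluation

RMSE = √mean((c−ĉ)²), MAE = mean|c−ĉ|, MAPE = mean(|c−ĉ|/|c|) reported
as a fraction (undefined when a true count is 0 — an explicit error
names the offending index), and the Pearson correlation r. Note the
square root in RMSE and the absolute value in MAPE: the metric names
and the ordering RMSE ≥ MAE require both. Group comparison is a
two-sided two-sample t-test, Welch's variant by default (the
application's group sizes are unequal); Student's pooled-variance
variant is available. Raw p-values are reported; no multiple-testing
correction.

## Desk-scale benchmark

Full-scale settings (256×256, 192/1000 epochs, 32-filter U-Net) are the
documented defaults but take GPU-days on CPU. The repository's
end-to-end check runs an easy benchmark chosen once for a single CPU:
96×96 scenes, counts uniform on [5, 50], radii 2–4 px, one corpus of
250 scenes carrying both annotation types (200 train / 50 test), U-Net
depth 2 with base 4 filters, mask AE filters (8, 8, 8), tail filters
(8, 12, 16, 16) with 32 dense units, feature stage 16 epochs and
regression stage 25 epochs at batch 8, learning rate 2e-3. Each
regression model is required to reach held-out Pearson r ≥ 0.8 as the
median over 3 seeds; observed values are ≈ 0.9–0.98, and the DDCNN
density-summation baseline on this easy regime reaches r ≈ 0.99.

## Numerical choices and edge cases

- Gaussian dot kernels are evaluated on a ±4σ window at pixel centers
  and normalized to mass α before placement; only border truncation
  removes mass, and the mass-conservation invariant (1%) is asserted
  for layouts ≥ 3σ from every border.
- Coordinates are row-major and 0-based; centers may be fractional.
- Max-pool gradient ties share the gradient equally; batch-norm uses
  eps 1e-3.
- Seeds flow through `numpy.random.SeedSequence` spawning, so datasets
  are reproducible per seed and independent across samples; dropout and
  shuffling use the training config's seed. Two runs with identical
  configs and seeds on one platform are bit-identical.
- Checkpoints are a JSON architecture descriptor plus an HDF5 weight
  container; save → load → predict is bit-stable, and shape mismatches
  between descriptor and weights raise.

## Known limitations

- Desk-scale absolute counts are attenuated a few tens of percent by
  the dropout/eval shift discussed above; rankings and correlations are
  unaffected.
- The mask branch's 8× bottleneck cannot localize 1–3 px cells
  precisely; at desk scale its decoded masks are coarse foreground
  estimates (the regression tail still extracts count signal from
  them).
- MAPE is undefined for images with zero true cells; the evaluation
  refuses rather than imputing.
- Training is single-threaded NumPy; the documented full-scale settings
  are provided for completeness, not speed.
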