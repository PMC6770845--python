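# ccens — cell counting by regression with ensembled deep imaging features

High-content microscopy experiments produce thousands of images whose
cell counts must be compared across experimental conditions — e.g.
organoid images from control vs. gene-overexpressing groups. Counting by
hand does not scale, and counting by detection degrades when cells clump
and overlap. `ccens` implements *counting by regression*: an image is
mapped to high-level imaging phenotypes, and those phenotypes are
regressed directly onto the integer count

- a **dot density map** D(x) — each cell contributes a Gaussian kernel
  of mass α, so count = Σ D/α — predicted by a U-Net branch;
- a **foreground mask** M(x) ∈ {0,1} — cell pixels vs. background —
  predicted by a convolutional autoencoder branch;
- an **ensembled** (stacked) model that concatenates both decoded
  phenotypes channel-wise and feeds them to one VGG-style regression
  tail (4 × [batch-norm → 3×3 conv + leaky ReLU → dropout 0.6 →
  max-pool], then two dense layers ending in a single linear unit).

Four models are assembled from these parts: **DRDCNN** (density branch →
tail), **FRDCNN** (mask branch → tail), **ERDCNN** (both branches,
concatenated, → two-channel tail) and the **DDCNN** baseline (density
branch only; count = Σ D̂/α, no tail). Training is two-stage: each branch
first learns its phenotype as an autoencoder (Adam/MSE); the branch is
then frozen bit-exactly and only the tail learns counts on the combined
corpus. The package also ships a synthetic-microscopy scene generator
(images + both annotation types + exact counts), corpus harmonization,
the RMSE/MAE/MAPE/Pearson-r evaluation suite, Welch/Student group
comparison, and a CLI. The neural-network machinery is a compact,
gradient-checked NumPy engine — no GPU or deep-learning framework
required.

## Worked example

Run the whole pipeline at desk scale from one config:

```yaml
# demo.yaml
seed: 7
image_size: 64
n_dot: 60
n_mask: 60
n_test_each: 15
dot_overrides:  {count_law: {kind: uniform_int, low: 5, high: 40}}
mask_overrides: {count_law: {kind: uniform_int, low: 5, high: 40}}
stage1: {epochs: 10, batch_size: 8, learning_rate: 2.0e-3}
stage2: {epochs: 20, batch_size: 8, learning_rate: 2.0e-3}
groups:
  names: [AKTP, AKTP-P2rX7, AKTP-Nt5e]
  sizes: [40, 30, 30]
  count_means: [30.0, 24.0, 30.0]
  count_sd: 8.0
```

```bash
ccens run --config demo.yaml --out demo
```

This simulates a dot-annotated and a mask-annotated corpus, harmonizes
them to 64×64, holds out a common 30-image test set, trains all four
models with the freeze/transfer procedure, and writes `metrics.csv`:

```
model,n,rmse,mae,mape,r
DRDCNN,30,8.3790,6.5292,0.3396,0.8736
FRDCNN,30,9.2351,7.5508,0.3547,0.8677
ERDCNN,30,9.2970,7.4280,0.3038,0.9068
DDCNN,30,6.7304,5.8135,0.2677,0.8509
```

Each row reports, on the held-out images, the root-mean-square error and
mean absolute error in cells, the mean absolute percent error as a
fraction, and the Pearson correlation between predicted and true counts
— here the ensembled model attains the highest correlation (r = 0.91)
after only a couple of minutes of CPU training.

Because `groups:` is set, the run also simulates three organoid-like
image groups whose true mean counts differ (the second group is shifted
down by 6), predicts their counts with the ensembled model, and writes
the two case-vs-control Welch t-tests to `compare.csv`:

```
model,group_a,group_b,mean_a,mean_b,t_stat,p_value,n_a,n_b
ERDCNN,AKTP-P2rX7,AKTP,11.3353,13.8522,-2.5401,1.373e-02,30,40
ERDCNN,AKTP-Nt5e,AKTP,12.3985,13.8522,-1.4916,1.410e-01,30,40
```

The genuinely shifted group is detected (p ≈ 0.014) while the null
group is not (p ≈ 0.14) — the model's absolute counts run low at desk
scale (see `docs/methods.md`), but group differences are preserved.

Individual stages are also available: `ccens simulate`,
`ccens preprocess`, `ccens train`, `ccens predict`, `ccens evaluate`,
`ccens compare`. The same functionality is importable
(`ccens.generate_dataset`, `ccens.train_full`, `ccens.evaluate_model`,
…).

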