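# tabseg

3D brain tissue segmentation (gray matter / white matter / CSF) with a
residual encoder/decoder network carrying a vision-transformer bottleneck,
plus its benchmark variants, a synthetic phantom generator, brain-masked
evaluation metrics, paired statistical comparison, and a test-retest
reliability protocol — all runnable end to end on CPU.

The default network maps a 192³ T1w volume through a 5-level encoder to a
128×12×12×12 bottleneck, tokenizes the 12³ spatial positions into 1,728
tokens of width 512 (linear projection + learned positional embedding), runs
a 4-layer / 8-head self-attention encoder, reshapes the 512×1,728 output back
to 512×12×12×12, reduces it to 128 channels by convolution, and decodes to a
3-channel probability map with a softmax head so per-voxel tissue
probabilities sum to 1. Four variants share depth and channel schedule:
`unet`, `unet_se` (squeeze-excitation before each downsampling), `resunet`
(residual blocks), and `tabs` (resunet + the transformer bottleneck).

Because no deep-learning framework is assumed, the networks run on a compact
numpy reverse-mode autodiff backend (`tabseg.nn`) with im2col-based 3D
convolutions; its gradients are verified against finite differences in the
test suite.

## Layout

| module                 | role |
|------------------------|------|
| `tabseg.phantom`       | synthetic skull-stripped T1w phantoms with exact GM/WM/CSF ground truth, partial-volume boundaries, bias fields, noise, retest pairs, 3:1:1 splits |
| `tabseg.preprocess`    | MIP-guided field-of-view pad/crop to a cubic frame, [-1, 1] intensity normalization, ground-truth channel stacking |
| `tabseg.model_zoo`     | the four model variants, shape tracing, tokenize/encode/detokenize |
| `tabseg.training`      | MSE regression training with Adam (lr 1e-5, weight decay 1e-6 defaults), early stopping, best-validation checkpointing |
| `tabseg.metrics`       | brain-restricted Pearson/Spearman/MSE and argmax-derived Dice/Jaccard/Hausdorff, per tissue |
| `tabseg.stats_compare` | paired two-sided Wilcoxon signed-rank tests (exact for n ≤ 25), significance stars, retest reliability |
| `tabseg.experiments`   | the desk-scale end-to-end benchmark (phantoms → train → evaluate → retest) |
| `tabseg.report`        | plain box-plot rendering with star annotations |
| `tabseg.io` / `tabseg.cli` | NIfTI-1 round trips, checkpoints, manifests, the `tabseg` command |

## CLI

```bash
tabseg phantom --n 10 --grid 64 --noise-sigma 0.02 --seed 1 --out-dir data/ --retest
tabseg train --variant tabs --data-dir data/ --out-dir run/ --config train.yaml --seed 1
tabseg predict --checkpoint run/checkpoint.npz --input data/sub-008_t1w.nii.gz --out pred.nii.gz
tabseg evaluate --pred pred.nii.gz --gt data/sub-008_probmap.nii.gz --out metrics.csv
tabseg compare --metrics-a tabs.csv --metrics-b unet.csv --out comparison.csv --plot-dir plots/
tabseg retest --pred-a a.nii.gz --pred-b b.nii.gz --mask data/sub-008_mask.nii.gz --out retest.csv
tabseg summary --variant tabs --grid 192
```

Volumes are NIfTI-1 (`.nii`/`.nii.gz`); probability maps are 4D NIfTI with
the channel axis last, channel order GM, WM, CSF recorded in the header.
Every stage writes a JSON manifest (config, seed, package version), and all
randomness derives from the given seed.

Example `train.yaml`:

```yaml
model:
  levels: 5
  bottleneck_features: 16
  channel_schedule: [4, 8, 16, 16, 16]
  embed_dim: 64
  transformer_layers: 2
  transformer_heads: 4
  norm_groups: 4
train:
  epochs: 20
  batch_size: 3
  lr: 0.001
```

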