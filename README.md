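# seedlingcounter

Small-object detection and stand counting for UAV crop imagery, built as a
reusable toolkit:

- **`rscconv`** — a self-calibrated convolution block: identity,
  original-scale 3×3, and 2×-upscaled-space 3×3 branches fused by
  elementwise multiplication, plus pretrained-weight inheritance and a
  backbone-patching adapter that swaps it into residual blocks.
- **`ascff`** — an adaptive spatial-channel fusion neck: three backbone
  levels are aligned to a common width and resolution, concatenated, passed
  through sequential channel-then-spatial attention, and reduced by a final
  feature-extraction convolution; one fusion per output scale, drop-in
  shape-compatible with a plain channel-mapper neck.
- **`detector`** — a compact, CPU-trainable single-class reference detector
  (center-heatmap head at stride 4) that hosts the patched backbone and the
  fusion neck so the three ablation axes (pretrained warm-up / RSCconv /
  ASCFF) can be exercised end to end at desk scale.
- **`tiling`** — a tile-and-stitch counting pipeline: 512×512 windows
  (edge windows shifted flush), greedy IoU de-duplication across overlaps,
  and two protocols — mode A (50 % overlap mosaic) and mode B (direct
  single-pass inference). Counting uses a strict `score > 0.5` rule.
- **`metrics`** — greedy COCO-style matching, 101-point interpolated AP,
  AP_50:95, size-stratified AP_S / AP_M with ignore semantics, and the
  counting metrics R², RMSE, MAE, MAPE.
- **`synthetic`** — a seeded generator of field-like scenes (row-structured
  green rosettes on correlated soil noise) with a controllable small/medium
  object-size mix, altitude (ground-sampling-distance) rescaling, the
  flip/resize/crop augmentation pipeline, 7:2:1 dataset splitting, and
  LabelMe→COCO annotation conversion — so everything is testable without
  any external dataset.

The neural stack runs on a small NumPy reverse-mode autodiff core
(`seedlingcounter.nn`) — no GPU or deep-learning framework required.

## CLI

```bash
# render a synthetic dataset (PNG + COCO ground truth + manifest CSV)
seedlingcounter generate --config field.yaml --n 200 --seed 7 --out data/

# train the reference detector
seedlingcounter train --config run.yaml --out runs/

# detect and count
seedlingcounter detect --checkpoint runs/checkpoint.npz --images data/ \
    --score-threshold 0.5 --out dets.json
seedlingcounter count --checkpoint runs/checkpoint.npz --images data/ \
    --mode A --overlap 0.5 --confidence 0.5 --out counts.csv

# desk-scale ablation on the standard synthetic benchmark
seedlingcounter ablate --toggles pretrained,rscconv,ascff --seeds 10
```

Config keys (YAML): `rscconv.enabled`, `rscconv.gate_calibration`,
`neck.type: ascff|channel_mapper`, `neck.out_channels`,
`neck.attention.reduction`, `neck.attention.spatial_kernel`, plus the
flat training fields (`learning_rate`, `weight_decay`, `epochs`,
`batch_size`, `backbone_lr_multiplier`, `seed`, ...).

## Design notes

- The reference detector substitutes a center-heatmap head for the original
  transformer decoder: the components under test live in the backbone and
  neck, and the head must train on one CPU in minutes.
- "Pretrained" at desk scale means a brief autoencoding warm-up of the
  backbone on a separate pool of synthetic scenes, standing in for
  ImageNet weights; flag semantics are identical.
- Scene realism is deliberately minimal. The generator reproduces the
  statistics that matter to the pipeline (tile geometry, size mix, row
  structure), not photorealism, and is not a substitute for real imagery.
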