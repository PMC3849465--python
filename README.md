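# hvsroi

Extraction of carcinoma-like regions of interest (RoIs) from
histopathology field-of-view images with a human-visual-system-inspired
pipeline:

1. **Bottom-up saliency** (`hvsroi.saliency`) — center–surround
   intensity, color-opponency and Gabor-orientation feature maps over a
   9-level Gaussian pyramid, promoted by a local-maxima normalization
   operator and combined into a saliency map in [0, 1].
2. **Region fusion** (`hvsroi.regions`) — deterministic superpixel
   segmentation (proximity + color similarity), a windowed
   Shannon-entropy "structural disorder" map, and per-region attention =
   mean saliency × normalized entropy.
3. **Target search** (`hvsroi.search`) — a database of 32×32 texton
   exemplars reduced to (I, O, C, H) feature vectors; regions are
   visited in decreasing attention order and classified by kNN majority
   vote over sampled textons until the first carcinoma-like region is
   found.
4. **Similarity propagation** (`hvsroi.propagation`) — every region
   whose scaled Euclidean feature distance `df` to the target falls
   under a threshold joins the RoI; the union becomes the output mask.

Because the original clinical images are not publicly deposited,
`hvsroi.fixtures` generates seeded histology-like images (basophilic
high-entropy "carcinoma" blobs on an eosinophilic low-entropy "stroma"
background) with ground-truth masks, and `hvsroi.evaluation` scores
predictions with pixel-level sensitivity/specificity.

## CLI

```bash
# Generate a synthetic fixture suite (images, masks, texton manifest)
rois-hvs make-fixtures --preset mag10 --n-train 1 --n-test 5 --seed 7 --out-dir fixtures/

# Build the texton database from the training images + manifest
rois-hvs build-db --train-dir fixtures/train --out db.json

# Run the full pipeline on one image
rois-hvs run --image fixtures/test/test_000.png --db db.json --seed 7 --out-dir out/

# Inspect intermediate stages
rois-hvs saliency --image fixtures/test/test_000.png --out-dir saliency/
rois-hvs segment  --image fixtures/test/test_000.png --out-dir segments/

# Score predicted masks against ground truth
rois-hvs evaluate --pred-dir preds/ --gt-dir gts/
```

Every knob (pyramid depth, center/surround scale set, superpixel count
and compactness, entropy window/bins, attention regulation mode, kNN
`k`, textons per region `m`, vote threshold, `df` threshold and feature
mask, seeds) lives in a YAML `PipelineConfig`; pass `--config file.yaml`
to any subcommand. Unknown keys are rejected.

## Outputs

`rois-hvs run` writes: `saliency.png`/`saliency.npy`, the three
conspicuity heatmaps, `entropy.png`, `regions.png` (16-bit label plane),
`regions.csv` (per-region area, I, O, C, H, mean saliency, attention),
`roi_mask.png`, `df.csv` (per-region distance to the target and
acceptance flag) and `run_summary.json` (config, seeds, versions,
no-target flag). Fixed config + seed gives byte-identical outputs.
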