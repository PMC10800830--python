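# ringseg

Automatic tree-ring boundary delineation on stained wood microsections, with
the evaluation metrics that matter for quantitative wood anatomy (QWA).

QWA measures xylem anatomy — above all, which vessels belong to which annual
ring — on high-resolution transverse microsections of tree cores (beech-like
imagery: ~1.63 µm/px, cores far taller than wide, ring boundaries visible as
bands of narrower fibers). Delineating those boundaries by hand is the
bottleneck. `ringseg` provides:

* a **UNETR segmentation model** — a vision-transformer encoder (P = 16
  image patches, embedding size K, pre-norm multi-head self-attention +
  GELU MLP blocks) feeding a UNET-style convolutional decoder through skip
  connections from four encoder depths, ending in a 1×1 convolution and
  sigmoid that scores every pixel as ring boundary or not. Implemented on a
  compact, gradient-checked numpy autodiff backend (`ringseg.nn`);
* the **Focal Tversky training loss**
  `L = (1 − TI)^γ`, `TI = Σyŷ / (Σyŷ + αΣy(1−ŷ) + βΣ(1−y)ŷ + ε)` with
  α = 0.7, β = 0.3, γ = 0.75, ε = 1e−12, suited to the extreme
  foreground/background imbalance of 1-px boundaries;
* **whole-image inference**: overlap-tile splitting (90% overlap by
  default), test-time augmentation over the 8 dihedral symmetries of the
  square with per-pixel max aggregation, min-max normalization and a 0.2
  threshold;
* **post-processing** to 1-px boundary polylines: topology-preserving
  skeletonization, Discrete Skeleton Evolution pruning (end-branches whose
  maximal-disk reconstruction contribution is under 100 px are removed),
  longest-geodesic path extraction;
* **QWA evaluation**: pixel agreement, mean-boundary-position spacing (px
  and µm), vessel-assignment mismatch between delineations, and expert
  trinomial agreement summaries;
* a **synthetic microsection generator** with exact ground truth (wavy
  fiber bands, semi-ring-porous vessel layout, Poisson vessel counts), so
  the full pipeline is testable end to end without any image downloads.

## Worked example

Score a model delineation against a manual one
(`examples/qwa_metrics.py` — two wavy boundaries, the model running 4 px low
on the first, 0.5 px off on the second, six vessels):

```
pixel agreement: precision 0.258 recall 0.258 F1 0.258 IoU 0.148
ring 0: center distance 4.00 px (6.52 um), vessel mismatch 2
ring 1: center distance 0.50 px (0.81 um), vessel mismatch 0
```

Pixel overlap is poor even for near-identical 1-px lines (two perfect
parallel lines one pixel apart score exactly 0) — which is why the spacing
and vessel criteria exist: ring 1 is QWA-equivalent to the manual version
(sub-pixel spacing, no vessel changes ring), while ring 0's 4-px offset
moves 2 vessel centers across the boundary.

Aggregating expert judgements (`examples/expert_agreement_table.py`, counts
108 / 619 / 601 of 1,329 rings):

```
  manual:  108 rings  (8.12%)
 similar:  619 rings  (46.57%)
   model:  601 rings  (45.22%)
equal or better than manual: 91.79%
```

Other examples: `generate_synthetic_core.py` (annotated synthetic core and
its ground truth), `train_tiny_segmenter.py` (a 111k-parameter UNETR whose
Focal Tversky loss falls from 0.80 to 0.67 in eight CPU epochs).

## Command line

Every stage is also a `ringseg` subcommand:

```sh
ringseg demo --out run/ --seed 7        # full synthetic loop, desk scale
ringseg generate --out data/ --n-images 4
ringseg prep --image X.tif --boundaries X.csv --out patches/ --stroke 3
ringseg train --patches patches/X_patches.npz --out ckpt/ --epochs 25
ringseg predict --image X.tif --ckpt ckpt/model.npz --out X_mask.png --threshold 0.2
ringseg postprocess --mask X_mask.png --out X_boundaries.csv --min-branch-area 100
ringseg evaluate --manual m.csv --predicted p.csv --vessels v.csv --out report/
```

`ringseg demo` generates four synthetic training cores (192×640 px, three
boundaries each), trains the small UNETR (K = 32, 4 layers) on ~200 patches
of 64×64 px, predicts three held-out cores with tiled TTA inference,
reduces the masks to boundary polylines and reports boundary recovery,
mean-center spacing and vessel mismatch. About 6 minutes on one CPU.

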