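# loiseg — cell instance segmentation from weak, machine-generatable annotations

`loiseg` trains single-cell instance segmentation models for 2-D
microscopy **without per-cell mask annotations**.  It targets the
common situation in quantitative cell biology where drawing thousands
of cell outlines is infeasible, but two much cheaper labels can be
produced programmably from the experiment itself:

* an **image-level segmentation** — one binary mask separating all
  cell pixels from background (e.g. a thresholded fluorescence
  channel), and
* **locations of interest (LOIs)** — one rough point per cell (e.g.
  nuclei detected in a DAPI channel with a difference-of-Gaussian blob
  detector, σ = 4.2/5 px).

## Method in brief

The model is a box-free, end-to-end instance segmenter with three
fully convolutional parts: an encoder/decoder **backbone** (feature
pyramid at strides 1/2/4), a **location proposal network** predicting
a cell-center heatmap with sub-stride offsets (no size regression —
LOIs carry no extent), and a per-cell **segmentation head** that runs
on a small crop around each proposed LOI, with a positional encoding
of each pixel *relative to the LOI* concatenated to the features so
different LOIs yield different cells.

Under weak supervision the segmentation head is trained by two
consistency terms over the per-cell soft masks `p_k`:

* the probabilistic union `q(x) = 1 − Π_k (1 − p_k(x))` must
  reproduce the image-level mask (cross-entropy), and
* pairwise overlap `Σ_x Σ_{j<k} p_j(x) p_k(x) / Σ_x q(x)` is
  penalized, so cells claim disjoint pixels.

A training-only, low-receptive-field **auxnet** is co-trained against
pseudo-boundaries of the model's own predictions and, through a
stop-gradient consistency term, sharpens the model's cell-cell
borders — useful exactly where touching cells make borders ambiguous.

Evaluation implements the standard instance metrics: average precision
`AP = (1/C) Σ_k P(k) T(k)` at IOU thresholds 0.50–0.95 (greedy
matching, no double-matching), mAP, the aggregated Jaccard index
(AJI), and detection precision/recall/F1 at IOU 0.6.

A deterministic synthetic-scene generator (dense fields of touching
textured ellipses with a correlated nucleus channel and configurable
annotation-error rates) makes the whole pipeline testable without any
external data.  See `docs/methods.md` for the full model, loss, and
generator description.

## Worked example

```python
import numpy as np
from loiseg import (SynthConfig, generate_scene, ModelConfig, TrainConfig,
                    TrainSample, train, segment_image, evaluate_instances)

# 1. a weakly annotated dataset: image-level masks + LOI lists only
scenes = [generate_scene(SynthConfig(image_size=96, n_cells_range=(7, 11),
                                     contact_fraction=0.4, seed=i))
          for i in range(32)]
ds = [TrainSample(image=s.image, weak=s.weak) for s in scenes]
val_scenes = [generate_scene(SynthConfig(image_size=96, n_cells_range=(7, 11),
                                         contact_fraction=0.4, seed=1000 + i))
              for i in range(8)]
val = [(s.image, s.instances) for s in val_scenes]

# 2. weak-supervision training with auxnet co-training
result = train(ModelConfig(seed=0),
               TrainConfig(mode="weak", epochs=15, seed=0, val_every=3),
               ds, val_dataset=val)

# 3. held-out evaluation
per_image, label_maps = [], []
for s in val_scenes:
    r = segment_image(s.image, result.model)
    per_image.append(([p.hard_mask(r.image_shape) for p in r.instances],
                      [p.score for p in r.instances], s.instances))
    label_maps.append(r.label_map)
rep = evaluate_instances(per_image, label_maps=label_maps)
print(f"AP50={rep.ap_by_iou[0.5]:.3f}  mAP={rep.map_score:.3f}  "
      f"AJI={rep.aji:.3f}  F1@0.6={rep.f1:.3f}")
```

Output on one CPU (≈2 minutes):

```
AP50=0.968  mAP=0.808  AJI=0.886  F1@0.6=0.945
```

i.e. trained from image masks and points alone, 97% of cells are
recovered at the IOU-0.5 criterion on held-out scenes, and the
pixel-level agreement (AJI 0.89) shows the per-cell shapes are close
to the painted ground truth.

The same pipeline is scriptable from the shell:

```
loiseg synth --n-images 32 --seed 0 --out data/
loiseg annotate detect-lois --nucleus data/scene_0000_nucleus.tif --out lois.csv
loiseg train --mode weak --data data/ --out run/
loiseg predict --image data/scene_0000_image.tif --weights run/final.ckpt \
               --out-labels pred.tif --out-json pred.json
loiseg evaluate --pred pred.json --gt data/scene_0000_labels.tif --report report.json
loiseg model describe
```

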