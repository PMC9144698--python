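# boxseg

Weakly supervised polyp segmentation from bounding-box annotations.

Pixel-level annotation of colonoscopy images is expensive; bounding boxes
are cheap. `boxseg` trains a U-Net style encoder–decoder to produce
pixel-level polyp masks using *only* box annotations, via iterative
pseudo-mask refinement: initial pseudo-masks are generated inside the boxes
(a solid circle, a pre-trained model's clipped prediction, or a hybrid of
the two), the network trains on them under a confidence-weighted masked
loss, and after each iteration the pseudo-masks are replaced by the
network's own thresholded predictions with every positive outside the boxes
removed. Box-supervised images can be pooled with mask-labeled images
(mixed supervision), whose targets stay fixed throughout training.

The core pieces:

* **Masked loss.** `Masked_Loss(P, Y, M) = Σ M ⊙ BCE(Y, P) / Σ M`, where
  the per-pixel weight `M ∈ [0,1]` is an oval ring spanning each box —
  zero along its midline, one at the box center and outside the box — so
  the network is scrutinized only where box supervision is trustworthy.
* **Refinement.** `target ← clip_to_boxes(P > 0.5)` after each training
  iteration; images with human masks are never rewritten.
* **Metrics.** Per-image dice coefficient, pixel accuracy and confusion
  counts, averaged over images, with k-fold cross-validation utilities.

The network is implemented as a small pure-NumPy convolutional engine
(im2col convolutions, transposed-convolution upsampling, Adam) with a
full-size VGG16-initializable preset and a first-class tiny preset
(~84k parameters, 96×96) so the entire training mechanism runs in minutes
on one CPU. A seeded synthetic scene generator (bright deformed-ellipse
"polyps" on textured backgrounds, with exact masks, tight or loosely
placed boxes, and instrument-like distractor bars) makes every experiment
reproducible offline.

## Worked example

```python
from boxseg import (benchmark_suite, evaluate_set, train_variant)
from boxseg.synthetic import benchmark_augment, benchmark_schedule

bench = benchmark_suite("recovery", seed=0)      # 200 train / 50 test scenes
model, history = train_variant(
    bench.split, "weak-ci",                       # circle initialization
    benchmark_schedule(epochs=(2, 2, 2, 2), seed=0),
    augment_cfg=benchmark_augment(96), seed=0)
report = evaluate_set(model, bench.split.test)
print(f"mean test dice {report['mean_dice']:.3f}")
```

prints

```
mean test dice 0.950
```

i.e. starting from solid-circle pseudo-masks whose own dice against the
hidden ground truth is ≈ 0.69, four refinement iterations recover the
polyp contours to a test dice of 0.95 — the model was never shown a single
true mask. The same comparison across initialization strategies (circle
vs. hybrid vs. mixed supervision) is run by
`scripts/acceptance.py` (below).

A command-line interface mirrors the workflows:

```bash
boxseg simulate --profile recovery --out data/ --seed 0
boxseg train --data data/ --variant weak-ci --seed 0 --out-dir runs/ci
boxseg evaluate --checkpoint runs/ci/model.npz --data data/
```

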