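# Methods

## The training problem

Semantic segmentation normally needs pixel-level masks. Here the
supervision for most images is an axis-aligned bounding box per polyp:
everything outside the box is guaranteed background, the box center is
almost certainly polyp, and the band near the box edges is uncertain. The
package turns this partial information into pixel-level training signal
through three mechanisms that interlock in an iterative loop:

1. **Pseudo-mask initialization.** Each box-annotated image receives a
   starting target: a solid circle centered in the box with diameter 4/5 of
   the box's shorter side (`circle`, CI); a pre-trained model's prediction
   thresholded strictly above 0.5 and clipped to the boxes (`prediction`,
   PI); or the prediction unless it covers less than 30% of a box's
   (continuous) area, in which case that box falls back to the circle
   (`hybrid`, HI). The 30% comparison is a strict less-than.
2. **Masked loss.** Training minimizes
   `Σ M ⊙ BCE(Y, P) / Σ M` with per-pixel weights `M`. For each box an
   oval ring is built: weight 0 along the ring midline, rising as
   `|d − d_mid|^1.5` (normalized by its grid maximum) inside the ring, and
   1 in the trusted core and outside the box. Per-box masks combine by
   element-wise minimum. Mask-labeled (fixed) images train with `M ≡ 1`:
   human masks carry no box-edge uncertainty.
3. **Refinement with external consistency.** After each iteration the
   targets of refinable images are replaced by the model's prediction
   thresholded at 0.5, with every positive pixel outside the box union set
   to zero. Fixed images are never rewritten. Early stopping ends training
   once the validation loss has failed to improve (tolerance 1e-5) for two
   consecutive iterations; box-only runs compute the validation loss with
   the same loss masks as training, so ground truth is never consulted
   before final evaluation.

## The two distance conventions of the ring mask

The published pseudo-code of the ring mask compares *squared* pixel
offsets (divided by an aspect-stretching factor) against *linear* radii
(`inner/outer_ring_diameter × box side / 2`). Taken literally, with O(1)
diameter factors the zero-confidence ring is only a few pixels wide near
the box center — it cannot "extend to the box edges" as the method's
description and its rationale require. `build_loss_mask` therefore
implements the printed arithmetic as its default (and tests verify it
against an independent scalar oracle), while the *training loop* defaults
to the Euclidean variant (`LossMaskParams(euclidean=True)`), which takes
the square root before comparing. Under the Euclidean form the defaults
`inner_ring_diameter = 0.6`, `outer_ring_diameter = 1.0` place the trusted
core at 0.3× the shorter box side and stretch the uncertainty ring exactly
to the box edges — the geometry the loss is meant to have. Both variants
are exposed through one flag.

## Network

A U-Net style encoder–decoder built on a small pure-NumPy layer engine
(same-padding 3×3 im2col convolutions with hand-coded backward passes, 2×2
max pooling, 2×2 stride-2 transposed convolutions, skip concatenations, a
1×1 sigmoid head, Adam). Two presets:

* `full_config()` — five encoder blocks of 64/128/256/512/512 channels
  with 2/2/3/3/3 convolutions (the VGG16 layout, so ImageNet-trained VGG16
  conv weights can be transplanted into the encoder from a local `.npz`
  file; nothing is ever downloaded), mirrored decoder, 384×384 input.
* `tiny_config()` — three blocks of 8/16/32 channels, two convolutions per
  block, 64-channel bottleneck, 96×96 input, ≈ 84k parameters. All tests
  and benchmarks run on this preset: the object of study is the training
  mechanism, not model capacity.

Training uses logits internally (`∂loss/∂z = M(σ(z) − y)/ΣM`), which is
algebraically identical to the clamped-probability loss that is reported
(clamp `ε = 1e-7`).

## Desk-scale study conditions

The published experiments train VGG16-pretrained networks on thousands of
real images; the package's benchmarks train the tiny preset from scratch
on synthetic scenes. Conditions adapted for that regime, fixed across all
benchmarks:

* Adam at `3e-3` (a from-scratch small-network rate; the published `1e-4`
  presumes a pretrained encoder), batch 12, per-epoch inverse-time decay
  `lr_e = lr_0 / (1 + 5e-4·e)` from the third iteration on. The published
  "decay with a factor of 0.0005 at each epoch" is read as inverse-time
  decay — the only reading under which learning continues over 40+ epochs.
* All four augmentations on: integer translations up to 60/384 of the
  image side (clamped so no box leaves the image), zoom ±10% about the
  image center, independent horizontal/vertical mirroring, and additive
  per-channel Gaussian color shifts (σ = 0.1) on normalized intensities.
  Masks use nearest-neighbor interpolation, images bilinear.
* Normalization by training-set per-channel mean/std (deterministic at
  inference); a per-image mode exists.
* Refinement and evaluation threshold 0.5 throughout, matching the
  initialization threshold.
* Optimizer state is kept across iterations (configurable).
* Benchmark problem sizes: recovery 200 train / 50 test at 96×96 with
  four 2-epoch iterations; the strategy-ordering comparison runs at
  64×64 with 100 train / 24 test over three seeds and the truncated
  published epoch plan (3, 3, 6). These sizes keep a full run in minutes
  on one CPU while preserving the phenomena under study.

## Degenerate-refinement guards

At desk scale a from-scratch model can still be underfit when the first
refinement fires; thresholding a weak prediction at 0.5 can then wipe out
most of the pseudo-mask area, after which training on near-empty targets
drives the model to all-background — an unrecoverable spiral the published
setting never encounters (a pretrained model always predicts something).
The loop applies the boxes' external-consistency logic symmetrically to
guard against this: exactly as positives outside a box are certainly wrong,
a pseudo-mask that (nearly) vanishes inside a box known to contain a polyp
is certainly wrong. Concretely, per image: a refined target whose area
falls below 25% of that image's previous target area is not accepted — the
previous target is kept (logged as `reverted_targets` in the run history)
and a later, better-fitted round replaces it. This is the per-box 30%
rejection rule of the hybrid initializer, transplanted to refinement time
and referenced to the previous mask instead of the box. Healthy refinement
rounds keep or grow the mask area (observed ratios ≈ 0.8–1.3), so the
guard is inert for them, and 25% still clears the largest legitimate
shrinkage step (a loose-box circle collapsing onto the true contour,
ratio ≈ 0.27 in the worst case). The `refine_targets` operation itself
still returns empty masks — the guard is loop policy.

The guard prevents silent target wipe-outs but not every failure: a
partially covering accepted target labels visually identical polyp texture
inconsistently, and the network can settle at an equilibrium probability
just below the 0.5 threshold (it localizes the polyp at p ≈ 0.45 but
thresholds to nothing). At an unlucky seed a circle-initialized box-only
run can therefore still end degenerate; better initialization (hybrid) or
mixed supervision removes this fragility — the ordering benchmark
demonstrates exactly that.

## Synthetic scenes

Each scene is a smooth random background (Gaussian-filtered noise around a
random base color) carrying one polyp: an ellipse (semi-minor axis
0.10–0.18 of the image side, eccentricity 1–2, random orientation) whose
radius is modulated by random-phase harmonics k = 2…5 with capped total
amplitude — so the region is star-convex, brighter than the background
(contrast 0.45) with its own texture, and deliberately *not* a circle:
circle initialization is informative but imperfect, which is what makes
the initialization-strategy comparison meaningful. Ground truth is the
exact rasterized region; the tight box is its bounding rectangle; loosely
placed boxes dilate each side by 50% (≈ 4× area); instrument-like bright
bars can cross the box without overwriting the polyp. All per-image
randomness derives from one seed via `SeedSequence` children, so datasets
are bit-identical across runs; tests additionally pin BLAS to one thread
so floating-point reductions are reproducible across machines.

What the generator does **not** emulate: real colonoscopy texture and
lighting, specular highlights, motion blur, multi-frame correlation, the
long tail of polyp morphologies, and annotation noise in the boxes
themselves. Passing benchmarks therefore demonstrate that the training
*mechanism* recovers contours from box supervision under controlled
conditions — not that any particular dice level transfers to clinical
data.

## Benchmarks and what they show

* **recovery** — circle-initialized box-only training must reach mean test
  dice ≥ 0.80 and beat the initial circle targets (dice ≈ 0.69) by ≥ 0.05.
  Measured: 0.95 at seed 0.
* **ordering** — with 30% loose boxes and 10% distractors, and a weak
  pre-trained initializer (the tiny net trained on 30 held-out scenes; 12
  epochs, enough to be functional — its weakness comes from the corrupted
  boxes, mirroring the published initializer whose weakness comes from
  domain shift): hybrid initialization must not trail circle
  initialization, and mixed supervision (32% of training images keep their
  true masks, the published 1300/4070 proportion) must not trail box-only
  training, as three-seed means with 0.02 noise tolerance. Measured
  margins are large (≈ +0.3), partly because circle initialization can
  still collapse at an unlucky seed while hybrid initialization and mixed
  supervision are robust — the same qualitative ordering the method
  reports at full scale.
* **smoke** — 20 scenes at 64×64 for wiring and in-loop invariant checks
  (no positive target pixel ever outside the box union; fixed targets
  bit-identical across iterations).

## Known limitations

* The pure-NumPy engine is single-threaded and desk-scale; the full-size
  preset is provided for completeness (one forward pass at 384×384 takes
  tens of seconds on one CPU).
* Box-only training from scratch remains collapse-prone at an unlucky
  seed even with the refinement guard (observed in roughly one of six
  benchmark seeds); better initialization or mixed supervision removes the
  fragility — which is itself one of the method's findings. The
  reproduction script averages the recovery benchmark over three derived
  seeds for this reason.
* Batch-norm-free stacks were chosen for determinism and simplicity; at
  desk scale they converge fine, at full scale normalization layers would
  likely be needed.
* Multi-polyp frames are supported throughout (union semantics for
  clipping, per-box loss masks combined by minimum, per-box hybrid
  decisions), but the benchmarks exercise predominantly single-polyp
  scenes.
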