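"""Seeded generator of polyp-like scenes for fully offline experiments.

Each scene is a smooth textured background carrying one (occasionally two)
bright, textured, deformed-ellipse "polyp" — an ellipse whose radius is
modulated by random-phase harmonics, so that a solid circle is an
informative but imperfect approximation of the region.  Every scene comes
with the exact rasterized ground-truth mask, the tight bounding rectangle
of that mask, optionally a loosely placed (dilated) box, and optionally an
instrument-like bright bar crossing the box.

All randomness flows from a single seed through per-image
``numpy.random.SeedSequence`` children, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .domain import AnnotatedImage, BoundingBox, DatasetSplit
from .pipeline import AugmentConfig
from .trainer import TrainedModel, TrainingSchedule, run_supervised_training
from .unet import UNetConfig, tiny_config

__all__ = [
    "SceneConfig",
    "generate_dataset",
    "benchmark_suite",
    "BenchmarkData",
    "apply_mix_labels",
]


@dataclass(frozen=True)
class SceneConfig:
    image_size: int = 96
    n_images: int = 50
    polyps_per_image: tuple = (1, 1)  # inclusive range; second polyp is rare
    polyp_axes_range: Optional[tuple] = None  # minor semi-axis, pixels
    polyp_eccentricity_range: tuple = (1.0, 2.0)
    intensity_contrast: float = 0.45
    background_texture_scale: float = 8.0
    loose_box_padding: float = 0.0  # per-side dilation as fraction of box side
    loose_box_fraction: float = 0.0  # fraction of images given loose boxes
    distractor_probability: float = 0.0
    two_polyp_probability: float = 0.05
    seed: int = 0

    def axes_range(self) -> tuple:
        if self.polyp_axes_range is not None:
            return self.polyp_axes_range
        return (max(3.0, 0.10 * self.image_size), 0.18 * self.image_size)


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal((size, size)), sigma=sigma, mode="reflect")
    std = noise.std()
    return noise / std if std > 0 else noise


def _polyp_mask(rng: np.random.Generator, size: int, cfg: SceneConfig) -> np.ndarray:
    """Rasterize one deformed ellipse; raises if it cannot fit the image."""
    lo, hi = cfg.axes_range()
    b = rng.uniform(lo, hi)
    ecc = rng.uniform(*cfg.polyp_eccentricity_range)
    a = min(b * ecc, 0.42 * size)
    theta = rng.uniform(0, np.pi)
    # radial harmonics; capped total amplitude keeps the region star-convex
    ks = np.array([2, 3, 4, 5])
    amps = rng.uniform(0, 0.10, size=ks.size) / np.sqrt(ks)
    if amps.sum() > 0.18:
        amps *= 0.18 / amps.sum()
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)
    margin = a * (1 + amps.sum()) + 2
    if 2 * margin >= size:
        raise ValueError(f"sampled polyp (semi-axis {a:.1f}px) cannot fit a {size}px image")
    cx = rng.uniform(margin, size - margin)
    cy = rng.uniform(margin, size - margin)

    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = np.hypot(u / a, v / b)
    phi = np.arctan2(v / b, u / a)
    r = 1.0 + sum(amp * np.cos(k * phi + ph) for amp, k, ph in zip(amps, ks, phases))
    return (rho < r).astype(np.uint8)


def _tight_box(mask: np.ndarray) -> BoundingBox:
    ys, xs = np.nonzero(mask)
    x_min, x_max = xs.min(), xs.max() + 1
    y_min, y_max = ys.min(), ys.max() + 1
    return BoundingBox.from_corner(float(x_min), float(y_min), float(x_max - x_min), float(y_max - y_min))


def _loosen(box: BoundingBox, padding: float, size: int) -> BoundingBox:
    x_min = max(box.x_min - padding * box.box_w, -0.5)
    x_max = min(box.x_max + padding * box.box_w, size - 0.5)
    y_min = max(box.y_min - padding * box.box_h, -0.5)
    y_max = min(box.y_max + padding * box.box_h, size - 0.5)
    return BoundingBox.from_corner(x_min, y_min, x_max - x_min, y_max - y_min)


def _draw_distractor(rng: np.random.Generator, image: np.ndarray, box: BoundingBox,
                     polyp_mask: np.ndarray) -> None:
    """Bright instrument-like bar crossing the box, never overwriting the polyp."""
    size = image.shape[0]
    angle = rng.uniform(0, np.pi)
    # the bar passes through a point near the box border
    px = box.center_x + rng.uniform(-0.5, 0.5) * box.box_w
    py = box.center_y + rng.uniform(-0.5, 0.5) * box.box_h
    nx, ny = -np.sin(angle), np.cos(angle)
    half_width = rng.uniform(1.2, 2.5)
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    dist = np.abs((xs - px) * nx + (ys - py) * ny)
    along = (xs - px) * np.cos(angle) + (ys - py) * np.sin(angle)
    length = rng.uniform(0.5, 1.0) * size
    bar = (dist < half_width) & (np.abs(along) < length / 2) & (polyp_mask == 0)
    shade = rng.uniform(0.82, 0.95)
    image[bar] = shade + rng.uniform(-0.03, 0.03, size=3)


def _generate_scene(child: np.random.SeedSequence, cfg: SceneConfig, index: int) -> AnnotatedImage:
    rng = np.random.default_rng(child)
    size = cfg.image_size
    base = rng.uniform(0.22, 0.42, size=3)
    texture = _smooth_noise(rng, size, cfg.background_texture_scale)
    fine = _smooth_noise(rng, size, 1.5)
    image = base[None, None, :] + 0.05 * texture[..., None] + 0.02 * fine[..., None]
    image += rng.normal(0, 0.01, size=image.shape)

    lo_n, hi_n = cfg.polyps_per_image
    n_polyps = lo_n
    if hi_n > lo_n and rng.random() < cfg.two_polyp_probability:
        n_polyps = hi_n
    gt = np.zeros((size, size), dtype=np.uint8)
    for _ in range(n_polyps):
        pm = _polyp_mask(rng, size, cfg)
        tint = rng.uniform(-0.06, 0.06, size=3)
        ptex = _smooth_noise(rng, size, 2.0)
        color = np.clip(base + cfg.intensity_contrast + tint, 0, 1)
        region = pm.astype(bool)
        image[region] = color[None, :] + 0.06 * ptex[region, None]
        gt |= pm

    tags = []
    tight_boxes = [_tight_box(gt)] if n_polyps == 1 else None
    if tight_boxes is None:
        # per-polyp boxes: re-derive from connected components
        from scipy.ndimage import label as cc_label

        lab, n_cc = cc_label(gt)
        tight_boxes = [_tight_box((lab == i).astype(np.uint8)) for i in range(1, n_cc + 1)]

    boxes = tight_boxes
    if cfg.loose_box_fraction > 0 and rng.random() < cfg.loose_box_fraction:
        boxes = [_loosen(b, cfg.loose_box_padding, size) for b in tight_boxes]
        tags.append("loose")
    if cfg.distractor_probability > 0 and rng.random() < cfg.distractor_probability:
        _draw_distractor(rng, image, boxes[0], gt)
        tags.append("distractor")

    image = gaussian_filter(image, sigma=(0.6, 0.6, 0))
    image = np.clip(image, 0, 1)
    im = AnnotatedImage(
        image_id=f"img_{index:05d}",
        pixels=image,
        boxes=boxes,
        gt_mask=gt,
        target=None,
        fixed_target=False,
        tags=tuple(tags),
    )
    im.validate()
    return im


def generate_dataset(cfg: SceneConfig) -> tuple:
    """Generate ``cfg.n_images`` scenes; returns ``(images, manifest)``."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_images)
    images = [_generate_scene(child, cfg, i) for i, child in enumerate(children)]
    manifest = {
        "generator": "boxseg.synthetic",
        "seed": cfg.seed,
        "image_size": cfg.image_size,
        "n_images": cfg.n_images,
        "images": [
            {"image_id": im.image_id, "tags": list(im.tags), "fixed_target": im.fixed_target}
            for im in images
        ],
    }
    return images, manifest


# ------------------------------------------------------------- benchmarks

def benchmark_schedule(epochs=(2, 2, 2, 2), seed: int = 0) -> TrainingSchedule:
    """Training schedule of the published procedure at desk scale: batch 12,
    per-epoch inverse-time lr decay (5e-4) from the third iteration on.  The
    learning rate is 3e-3 — appropriate for a small network trained from
    scratch, where the published 1e-4 presumes a large pretrained encoder."""
    return TrainingSchedule(
        epochs_per_iteration=list(epochs), batch_size=12, initial_lr=3e-3,
        lr_decay=5e-4, decay_start_iteration=3, seed=seed,
    )


def benchmark_augment(image_size: int) -> AugmentConfig:
    """The four training augmentations with the translation limit scaled to
    the image side (60 px on a 384 px image = 15.6% of the side)."""
    return AugmentConfig(
        max_translation=max(1, round(60 * image_size / 384)),
        zoom_range=0.10,
        color_shift_std=0.1,
    )


@dataclass
class BenchmarkData:
    split: DatasetSplit
    config: SceneConfig
    init_model: Optional[TrainedModel] = None


def apply_mix_labels(split: DatasetSplit, fraction: float, seed: int = 0) -> DatasetSplit:
    """Return a copy of the split where a seeded fraction of the training
    images keep their ground-truth mask as a *fixed* target (mixed
    supervision); the rest stay box-only and refinable."""
    rng = np.random.default_rng(seed)
    train = [replace_image(im) for im in split.train]
    n_fixed = int(round(fraction * len(train)))
    order = rng.permutation(len(train))
    for idx in order[:n_fixed]:
        im = train[idx]
        if im.gt_mask is None:
            raise ValueError(f"{im.image_id}: cannot fix target without gt_mask")
        im.fixed_target = True
        im.target = im.gt_mask.copy()
    return DatasetSplit(train, list(split.validation), list(split.test), split.fold_index)


def replace_image(im: AnnotatedImage) -> AnnotatedImage:
    return AnnotatedImage(
        image_id=im.image_id,
        pixels=im.pixels,
        boxes=list(im.boxes),
        gt_mask=im.gt_mask,
        target=None if im.target is None else im.target.copy(),
        fixed_target=im.fixed_target,
        tags=im.tags,
    )


PROFILES = {
    "smoke": dict(image_size=64, n_train=14, n_val=2, n_test=4),
    "recovery": dict(image_size=96, n_train=200, n_val=0, n_test=50),
    "ordering": dict(image_size=96, n_train=200, n_val=0, n_test=50,
                     loose_box_fraction=0.3, loose_box_padding=0.5,
                     distractor_probability=0.1, n_init=30),
}


def benchmark_suite(
    profile: str,
    seed: int = 0,
    image_size: Optional[int] = None,
    n_train: Optional[int] = None,
    n_val: Optional[int] = None,
    n_test: Optional[int] = None,
    init_epochs: int = 12,
) -> BenchmarkData:
    """Fixed published benchmark configurations.

    * ``smoke`` — 20 images at 64x64, for end-to-end wiring checks.
    * ``recovery`` — 200 train / 50 test at 96x96, tight boxes: measures
      whether iterative refinement recovers contours from circle targets.
    * ``ordering`` — recovery conditions plus 30% loosely placed boxes and
      10% instrument distractors, together with a deliberately weak
      pre-trained initializer (trained on 30 held-out images) to feed the
      prediction/hybrid strategies.

    Sizes may be overridden for scaled-down runs; ground-truth masks are
    attached to every image but all images are refinable (weak supervision)
    until :func:`apply_mix_labels` is applied.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    p = dict(PROFILES[profile])
    size = image_size or p["image_size"]
    counts = {
        "n_train": n_train if n_train is not None else p["n_train"],
        "n_val": n_val if n_val is not None else p["n_val"],
        "n_test": n_test if n_test is not None else p["n_test"],
    }
    n_init = p.get("n_init", 0)
    total = counts["n_train"] + counts["n_val"] + counts["n_test"] + n_init
    cfg = SceneConfig(
        image_size=size,
        n_images=total,
        loose_box_fraction=p.get("loose_box_fraction", 0.0),
        loose_box_padding=p.get("loose_box_padding", 0.0),
        distractor_probability=p.get("distractor_probability", 0.0),
        seed=seed,
    )
    images, _ = generate_dataset(cfg)
    a = counts["n_train"]
    b = a + counts["n_val"]
    c = b + counts["n_test"]
    split = DatasetSplit(train=images[:a], validation=images[a:b], test=images[b:c])

    init_model = None
    if n_init:
        held_out = images[c : c + n_init]
        for im in held_out:
            im.fixed_target = True
            im.target = im.gt_mask.copy()
        init_split = DatasetSplit(train=held_out, validation=[], test=[])
        schedule = TrainingSchedule(
            epochs_per_iteration=[init_epochs], batch_size=8, initial_lr=3e-3,
            decay_start_iteration=10, seed=seed,
        )
        init_model, _ = run_supervised_training(
            init_split, schedule, model_cfg=tiny_config(), seed=seed
        )
    return BenchmarkData(split=split, config=cfg, init_model=init_model)
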