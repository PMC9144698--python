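"""Initial pseudo-mask generation for box-annotated images.

Three strategies seed the iterative refinement loop:

* ``circle`` (CI) — a solid disc centered in each box, diameter a fixed
  fraction (default 4/5) of the box's shorter side;
* ``prediction`` (PI) — a pre-trained segmentation model's prediction,
  thresholded and clipped to the boxes;
* ``hybrid`` (HI) — the prediction, unless it covers less than a minimum
  fraction (default 30%) of a box's area, in which case that box falls back
  to the circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .domain import (
    AnnotatedImage,
    BoundingBox,
    clip_mask_to_boxes,
    validate_probability_map,
)

__all__ = [
    "InitializerConfig",
    "circle_init",
    "prediction_init",
    "hybrid_init",
    "initialize_targets",
]

STRATEGIES = ("circle", "prediction", "hybrid")


@dataclass(frozen=True)
class InitializerConfig:
    strategy: str = "circle"
    circle_diameter_fraction: float = 0.8
    prediction_threshold: float = 0.5
    hybrid_area_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if not 0 < self.circle_diameter_fraction <= 1:
            raise ValueError("circle_diameter_fraction must be in (0, 1]")
        if not 0 < self.prediction_threshold < 1:
            raise ValueError("prediction_threshold must be in (0, 1)")
        if not 0 < self.hybrid_area_fraction < 1:
            raise ValueError("hybrid_area_fraction must be in (0, 1)")


def _disc(box: BoundingBox, width: int, height: int, diameter: float) -> np.ndarray:
    """Pixels whose centers lie strictly inside the disc centered on the box."""
    r = diameter / 2.0
    ys = np.arange(height, dtype=float)[:, None]
    xs = np.arange(width, dtype=float)[None, :]
    inside = (xs - box.center_x) ** 2 + (ys - box.center_y) ** 2 < r * r
    return inside.astype(np.uint8)


def circle_init(
    box: BoundingBox, width: int, height: int, cfg: InitializerConfig = InitializerConfig()
) -> np.ndarray:
    """Solid disc centered in the box; all positives stay inside the box."""
    diameter = cfg.circle_diameter_fraction * min(box.box_w, box.box_h)
    if diameter < 1.0:
        raise ValueError(
            f"circle diameter {diameter:.2f}px < 1px for box {box}; annotation too small"
        )
    mask = _disc(box, width, height, diameter)
    # the disc is geometrically contained in the box; clip anyway so the
    # positives-within-boxes invariant holds even for boxes cropped by the
    # image border
    return clip_mask_to_boxes(mask, [box])


def prediction_init(
    prob: np.ndarray,
    boxes: Sequence[BoundingBox],
    cfg: InitializerConfig = InitializerConfig(strategy="prediction"),
) -> np.ndarray:
    """Threshold a probability map (strictly above threshold) and clip to boxes."""
    prob = validate_probability_map(prob)
    mask = (prob > cfg.prediction_threshold).astype(np.uint8)
    return clip_mask_to_boxes(mask, boxes)


def hybrid_init(
    prob: np.ndarray,
    boxes: Sequence[BoundingBox],
    width: int,
    height: int,
    cfg: InitializerConfig = InitializerConfig(strategy="hybrid"),
) -> np.ndarray:
    """Per box: keep the clipped prediction if it covers at least the
    configured fraction of the (continuous) box area, else fall back to the
    circle.  Multi-box images decide per box and union the results."""
    prob = validate_probability_map(prob)
    thresholded = (prob > cfg.prediction_threshold).astype(np.uint8)
    out = np.zeros((height, width), dtype=np.uint8)
    for box in boxes:
        in_box = clip_mask_to_boxes(thresholded, [box])
        area_fraction = float(in_box.sum()) / box.area
        if area_fraction < cfg.hybrid_area_fraction:
            piece = circle_init(box, width, height, cfg)
        else:
            piece = in_box
        out |= piece
    return out


def initialize_targets(
    images: Sequence[AnnotatedImage],
    cfg: InitializerConfig,
    predict=None,
) -> list:
    """Set the initial training target on every refinable image, in place.

    ``predict`` is a callable mapping an ``AnnotatedImage`` to a probability
    map; it is required for the prediction and hybrid strategies.  Images
    with ``fixed_target=True`` keep their human mask untouched.

    Returns a per-image log of the source actually used (``circle`` /
    ``prediction``), mirroring the observation that a hybrid initialization
    typically yields a mix of both.
    """
    if cfg.strategy in ("prediction", "hybrid") and predict is None:
        raise ValueError(f"strategy {cfg.strategy!r} needs a pre-trained predictor")
    log = []
    for im in images:
        if im.fixed_target:
            log.append({"image_id": im.image_id, "source": "fixed"})
            continue
        if not im.boxes:
            raise ValueError(f"{im.image_id}: refinable image has no boxes")
        h, w = im.pixels.shape[:2]
        if cfg.strategy == "circle":
            masks = [circle_init(b, w, h, cfg) for b in im.boxes]
            target = np.zeros((h, w), dtype=np.uint8)
            for m in masks:
                target |= m
            source = "circle"
        else:
            prob = predict(im)
            if cfg.strategy == "prediction":
                target = prediction_init(prob, im.boxes, cfg)
                source = "prediction"
            else:
                target = hybrid_init(prob, im.boxes, w, h, cfg)
                # report whether any box fell back to the circle
                kept = all(
                    float(clip_mask_to_boxes((prob > cfg.prediction_threshold).astype(np.uint8), [b]).sum())
                    / b.area
                    >= cfg.hybrid_area_fraction
                    for b in im.boxes
                )
                source = "prediction" if kept else "circle"
        im.target = target
        log.append({"image_id": im.image_id, "source": source})
    return log
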