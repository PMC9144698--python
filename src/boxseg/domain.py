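"""Shared geometric and annotation types.

Coordinate convention used throughout the package: pixel ``(0, 0)`` is the
*center* of the top-left pixel, ``x`` indexes columns and ``y`` indexes rows.
Bounding boxes are continuous axis-aligned rectangles, half-open on the max
side; a pixel is *inside* a box iff its integer center satisfies
``x_min <= x < x_max`` and ``y_min <= y < y_max``.  The continuous image
extent is ``[-0.5, W - 0.5) x [-0.5, H - 0.5)``.

Binary masks are 2-D ``uint8`` arrays with values in ``{0, 1}``; probability
maps are 2-D float arrays in ``[0, 1]``.  Both are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "AnnotatedImage",
    "DatasetSplit",
    "GeometricTransform",
    "clip_mask_to_boxes",
    "box_union_mask",
    "validate_binary_mask",
    "validate_probability_map",
]


def validate_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is a 2-D {0,1} array; return it as uint8."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"binary mask must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("binary mask values must be exactly 0 or 1")
    return mask.astype(np.uint8, copy=False)


def validate_probability_map(prob: np.ndarray) -> np.ndarray:
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 2:
        raise ValueError(f"probability map must be 2-D, got shape {prob.shape}")
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return prob


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle locating one polyp.

    Stored by center and side lengths (all in pixels, continuous).
    """

    center_x: float
    center_y: float
    box_w: float
    box_h: float

    def __post_init__(self) -> None:
        if self.box_w <= 0 or self.box_h <= 0:
            raise ValueError(
                f"box sides must be positive, got {self.box_w} x {self.box_h}"
            )

    @classmethod
    def from_corner(cls, x_min: float, y_min: float, box_w: float, box_h: float) -> "BoundingBox":
        return cls(x_min + box_w / 2.0, y_min + box_h / 2.0, box_w, box_h)

    @property
    def x_min(self) -> float:
        return self.center_x - self.box_w / 2.0

    @property
    def x_max(self) -> float:
        return self.center_x + self.box_w / 2.0

    @property
    def y_min(self) -> float:
        return self.center_y - self.box_h / 2.0

    @property
    def y_max(self) -> float:
        return self.center_y + self.box_h / 2.0

    @property
    def area(self) -> float:
        return self.box_w * self.box_h

    def intersects_image(self, width: int, height: int) -> bool:
        return (
            self.x_min < width - 0.5
            and self.x_max > -0.5
            and self.y_min < height - 0.5
            and self.y_max > -0.5
        )

    def inside_grid(self, width: int, height: int) -> np.ndarray:
        """Boolean (height, width) array: pixel centers inside the box."""
        xs = np.arange(width)
        ys = np.arange(height)
        in_x = (xs >= self.x_min) & (xs < self.x_max)
        in_y = (ys >= self.y_min) & (ys < self.y_max)
        return in_y[:, None] & in_x[None, :]


def box_union_mask(boxes: Sequence[BoundingBox], width: int, height: int) -> np.ndarray:
    """uint8 (height, width) mask of pixels inside any box; zeros if no boxes."""
    out = np.zeros((height, width), dtype=bool)
    for box in boxes:
        out |= box.inside_grid(width, height)
    return out.astype(np.uint8)


def clip_mask_to_boxes(mask: np.ndarray, boxes: Sequence[BoundingBox]) -> np.ndarray:
    """Zero every positive pixel whose center lies outside all boxes.

    Negatives are never modified; an empty box list yields the all-zero mask.
    """
    mask = validate_binary_mask(mask)
    height, width = mask.shape
    union = box_union_mask(boxes, width, height)
    return (mask & union).astype(np.uint8)


@dataclass
class AnnotatedImage:
    """One image with its annotations and current training target.

    ``fixed_target`` marks images whose target is a trusted human mask: the
    refinement loop must never rewrite them.  ``tags`` supports subset
    evaluation (e.g. scoring only a difficult histology class).
    """

    image_id: str
    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    boxes: list = field(default_factory=list)
    gt_mask: Optional[np.ndarray] = None
    target: Optional[np.ndarray] = None
    fixed_target: bool = False
    tags: tuple = ()

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def validate(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"{self.image_id}: pixels must be (H, W, 3)")
        h, w = self.pixels.shape[:2]
        for box in self.boxes:
            if not box.intersects_image(w, h):
                raise ValueError(f"{self.image_id}: box {box} outside image extent")
        for name, m in (("gt_mask", self.gt_mask), ("target", self.target)):
            if m is not None:
                m = validate_binary_mask(m)
                if m.shape != (h, w):
                    raise ValueError(f"{self.image_id}: {name} shape {m.shape} != image {h, w}")
        if self.fixed_target:
            if self.gt_mask is None:
                raise ValueError(f"{self.image_id}: fixed_target requires gt_mask")
            if self.target is None or not np.array_equal(self.target, self.gt_mask):
                raise ValueError(f"{self.image_id}: fixed target must equal gt_mask")
        if self.target is not None and self.boxes:
            union = box_union_mask(self.boxes, w, h)
            if np.any((self.target == 1) & (union == 0)):
                raise ValueError(f"{self.image_id}: target positives outside box union")


@dataclass
class DatasetSplit:
    """Train/validation/test partition for one cross-validation fold."""

    train: list
    validation: list
    test: list
    fold_index: int = 0

    def __post_init__(self) -> None:
        ids: list[str] = []
        for part in (self.train, self.validation, self.test):
            ids.extend(im.image_id for im in part)
        if len(ids) != len(set(ids)):
            raise ValueError("dataset split lists are not disjoint by image_id")

    def all_images(self) -> list:
        return list(self.train) + list(self.validation) + list(self.test)


@dataclass(frozen=True)
class GeometricTransform:
    """Axis-aligned affine map ``x' = ax*x + bx``, ``y' = ay*y + by``.

    Negative ``ax``/``ay`` encode mirroring.  Covers every geometric
    operation the training pipeline uses (translate, zoom, flips,
    resize-and-pad); carries the output image size so transformed boxes can
    be validated.
    """

    ax: float
    bx: float
    ay: float
    by: float
    out_width: int
    out_height: int
    src_width: Optional[int] = None
    src_height: Optional[int] = None

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, width: int, height: int) -> "GeometricTransform":
        return cls(1.0, 0.0, 1.0, 0.0, width, height, width, height)

    @classmethod
    def hflip(cls, width: int, height: int) -> "GeometricTransform":
        # mirror about the grid center (W-1)/2, consistent with np.fliplr
        return cls(-1.0, float(width - 1), 1.0, 0.0, width, height, width, height)

    @classmethod
    def vflip(cls, width: int, height: int) -> "GeometricTransform":
        return cls(1.0, 0.0, -1.0, float(height - 1), width, height, width, height)

    @classmethod
    def translate(cls, dx: float, dy: float, width: int, height: int) -> "GeometricTransform":
        return cls(1.0, float(dx), 1.0, float(dy), width, height, width, height)

    @classmethod
    def zoom(cls, factor: float, width: int, height: int) -> "GeometricTransform":
        """Scale by ``factor`` about the image grid center."""
        if factor <= 0:
            raise ValueError("zoom factor must be positive")
        cx = (width - 1) / 2.0
        cy = (height - 1) / 2.0
        return cls(factor, cx * (1 - factor), factor, cy * (1 - factor),
                   width, height, width, height)

    @classmethod
    def resize_pad(cls, src_height: int, src_width: int, target_size: int) -> "GeometricTransform":
        """Aspect-preserving scale to ``target_size`` on the long side plus
        symmetric zero padding to a square.  Pixel-center accurate:
        ``x' = (x + 0.5) * s - 0.5 + pad``."""
        s = target_size / max(src_height, src_width)
        new_w = round(src_width * s)
        new_h = round(src_height * s)
        pad_x = (target_size - new_w) / 2.0
        pad_y = (target_size - new_h) / 2.0
        return cls(s, 0.5 * s - 0.5 + pad_x, s, 0.5 * s - 0.5 + pad_y,
                   target_size, target_size, src_width, src_height)

    # -- application --------------------------------------------------
    def apply_point(self, x: float, y: float) -> tuple:
        return self.ax * x + self.bx, self.ay * y + self.by

    def apply_box(self, box: BoundingBox) -> BoundingBox:
        cx, cy = self.apply_point(box.center_x, box.center_y)
        new = BoundingBox(cx, cy, box.box_w * abs(self.ax), box.box_h * abs(self.ay))
        if not new.intersects_image(self.out_width, self.out_height):
            raise ValueError(f"transformed box {new} no longer intersects the image")
        return new

    def inverse(self) -> "GeometricTransform":
        """Inverse map, validating boxes against the source frame."""
        return GeometricTransform(
            1.0 / self.ax,
            -self.bx / self.ax,
            1.0 / self.ay,
            -self.by / self.ay,
            self.src_width if self.src_width is not None else self.out_width,
            self.src_height if self.src_height is not None else self.out_height,
            self.out_width,
            self.out_height,
        )

    def with_out_size(self, width: int, height: int) -> "GeometricTransform":
        return replace(self, out_width=width, out_height=height)

    def compose(self, first: "GeometricTransform") -> "GeometricTransform":
        """Return the transform applying ``first`` then ``self``."""
        return GeometricTransform(
            self.ax * first.ax,
            self.ax * first.bx + self.bx,
            self.ay * first.ay,
            self.ay * first.by + self.by,
            self.out_width,
            self.out_height,
        )


def transform_box(box: BoundingBox, transform: GeometricTransform) -> BoundingBox:
    """Map a box through an image transform, keeping it aligned with the
    identically transformed image; raises if the result leaves the image."""
    return transform.apply_box(box)
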