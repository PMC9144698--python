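"""Ring-shaped confidence weight masks and the masked training loss.

Box-derived training targets are unreliable near the box edges: the box
interior close to its border may or may not belong to the polyp, while the
box center almost surely does and everything outside the box surely does
not.  The loss mask ``M`` encodes this as a per-pixel weight in ``[0, 1]``:
an oval ring spanning the box is weighted 0 along its midline, ramping up to
1 at the box center and outside the box, so the masked loss scrutinizes the
network only where the weak labels are trustworthy.

The mask construction is implemented exactly as published, including its
hybrid distance measure (squared pixel offsets divided by an aspect
stretching, compared against *linear* radii).  A conventional Euclidean
variant is available behind the non-default ``euclidean`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .domain import BoundingBox

__all__ = [
    "LossMaskParams",
    "build_loss_mask",
    "combine_loss_masks",
    "loss_mask_for_image",
    "masked_loss",
    "BCE_EPS",
]

#: probability clamp for the binary cross-entropy (the loss is undefined at 0/1)
BCE_EPS = 1e-7

#: default weighting used by the *training loop*: the Euclidean-distance ring,
#: which spans the trusted box core out to the box edges as the method's
#: description requires (the as-printed formula remains the operation default)
def training_loss_params() -> "LossMaskParams":
    return LossMaskParams(euclidean=True)


@dataclass(frozen=True)
class LossMaskParams:
    """Scale factors of the confidence ring.

    ``outer_ring_diameter = 1.0`` makes the ring extend to the box edges;
    ``inner_ring_diameter`` sets the size of the fully trusted core.  The
    ramp exponent shapes the transition between the zero-confidence midline
    and the trusted regions.
    """

    inner_ring_diameter: float = 0.6
    outer_ring_diameter: float = 1.0
    ramp_exponent: float = 1.5
    euclidean: bool = False

    def __post_init__(self) -> None:
        if self.inner_ring_diameter <= 0 or self.outer_ring_diameter <= 0:
            raise ValueError("ring diameters must be positive")

    def radii(self, box: BoundingBox) -> tuple:
        inner = min(box.box_w, box.box_h) * self.inner_ring_diameter * 0.5
        outer = max(box.box_w, box.box_h) * self.outer_ring_diameter * 0.5
        return inner, outer


def build_loss_mask(
    box: BoundingBox, width: int, height: int, params: LossMaskParams = LossMaskParams()
) -> np.ndarray:
    """Build the (height, width) per-pixel weight grid for one box.

    Raises ``ValueError`` if the ring region contains no pixel centers (the
    ramp normalization would divide by zero) — a symptom of a degenerate or
    badly placed box that should be surfaced, not hidden.
    """
    inner_radius, outer_radius = params.radii(box)
    if inner_radius >= outer_radius:
        raise ValueError(
            f"inner radius {inner_radius} must be below outer radius {outer_radius}"
        )
    ys = np.arange(height, dtype=float)[:, None]
    xs = np.arange(width, dtype=float)[None, :]
    if box.box_w >= box.box_h:
        x_stretching = box.box_w / box.box_h
        y_stretching = 1.0
    else:
        x_stretching = 1.0
        y_stretching = box.box_h / box.box_w
    # same spelling as the published pseudo-code (0-based grid, the box
    # center expressed in the same frame — a pure translation)
    dist_from_center = (xs - box.center_x) ** 2 / x_stretching + (
        ys - box.center_y
    ) ** 2 / y_stretching
    if params.euclidean:
        dist_from_center = np.sqrt(dist_from_center)
    inv_mask = (dist_from_center < outer_radius) & (inner_radius < dist_from_center)
    inv_mask = inv_mask.astype(float)
    midline = (outer_radius + inner_radius) / 2.0
    ramp = np.abs(dist_from_center - midline) ** params.ramp_exponent * inv_mask
    peak = ramp.max()
    if peak == 0.0:
        raise ValueError(
            f"ring region of box {box} contains no pixel centers; cannot normalize"
        )
    return ramp / peak + (1.0 - inv_mask)


def combine_loss_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise minimum of per-box masks (most-conservative weight wins)."""
    if len(masks) == 0:
        raise ValueError("cannot combine an empty list of loss masks")
    out = np.asarray(masks[0], dtype=float)
    for m in masks[1:]:
        m = np.asarray(m, dtype=float)
        if m.shape != out.shape:
            raise ValueError("loss masks to combine must share dimensions")
        out = np.minimum(out, m)
    return out


def loss_mask_for_image(
    boxes: Sequence[BoundingBox],
    width: int,
    height: int,
    params: LossMaskParams = LossMaskParams(),
) -> np.ndarray:
    """Combined weight grid for an image with one or more boxes."""
    if not boxes:
        raise ValueError("image has no boxes; cannot build a loss mask")
    return combine_loss_masks([build_loss_mask(b, width, height, params) for b in boxes])


def masked_loss(P: np.ndarray, Y: np.ndarray, M: np.ndarray, eps: float = BCE_EPS) -> float:
    """Weighted binary cross-entropy, normalized by the total weight:

        loss = sum(M * BCE(Y, P)) / sum(M)

    with ``BCE(y, p) = -[y ln p + (1-y) ln(1-p)]`` and ``p`` clamped to
    ``[eps, 1-eps]``.  Accepts single grids or batches; all three arrays must
    share dimensions.
    """
    P = np.asarray(P, dtype=float)
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=float)
    if not (P.shape == Y.shape == M.shape):
        raise ValueError(f"shape mismatch: P {P.shape}, Y {Y.shape}, M {M.shape}")
    total = M.sum()
    if total <= 0.0:
        raise ValueError("sum of loss-mask weights is zero; loss undefined")
    p = np.clip(P, eps, 1.0 - eps)
    bce = -(Y * np.log(p) + (1.0 - Y) * np.log(1.0 - p))
    return float((M * bce).sum() / total)
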