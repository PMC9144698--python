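"""Dataset I/O, preprocessing and augmentation.

Annotation dialect: boxes are stored in a CSV with header
``image_id,x_min,y_min,box_w,box_h`` (0-based pixels, min-corner form;
centers are derived).  Masks are single-channel 8-bit PNGs with 0 =
background and 255 = polyp.  Images are 8-bit RGB PNG/JPEG, loaded as
floats in [0, 1].

Preprocessing resizes and pads every image to a square (default 384x384,
aspect preserved, symmetric zero padding) and normalizes by per-channel
mean/std — either statistics of the training set (default, deterministic at
inference) or per image.  Four augmentations are supported: integer
translations clamped so no box leaves the image, zoom about the image
center, horizontal/vertical mirroring, and additive per-channel Gaussian
color shifts applied on normalized intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .domain import AnnotatedImage, BoundingBox, GeometricTransform, transform_box

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "load_dataset",
    "save_dataset",
    "compute_dataset_stats",
    "normalize_image",
    "resize_and_pad",
    "augment",
    "read_mask",
    "write_mask",
    "write_probability_map",
]


@dataclass
class PreprocessConfig:
    target_size: int = 384
    normalization: str = "dataset-stats"  # or "per-image"
    dataset_mean: Optional[tuple] = None
    dataset_std: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.normalization not in ("dataset-stats", "per-image"):
            raise ValueError("normalization must be 'dataset-stats' or 'per-image'")


@dataclass
class AugmentConfig:
    max_translation: int = 60
    zoom_range: float = 0.10
    flip_horizontal: bool = True
    flip_vertical: bool = True
    color_shift_std: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")
        if not 0 <= self.zoom_range < 1:
            raise ValueError("zoom_range must be in [0, 1)")


# ---------------------------------------------------------------- file I/O

def read_mask(path) -> np.ndarray:
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    values = np.unique(raw)
    if not np.isin(values, (0, 255)).all():
        raise ValueError(f"{path}: mask values must be 0 or 255, found {values[:10]}")
    return (raw == 255).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def write_probability_map(path, prob: np.ndarray) -> None:
    """Canonical lossy export: 8-bit PNG of round(255 * p)."""
    iio.imwrite(path, np.round(np.clip(prob, 0, 1) * 255).astype(np.uint8))


def write_probability_array(path, prob: np.ndarray) -> None:
    """Lossless float export (.npz) for exact comparisons."""
    np.savez(path, probability=np.asarray(prob, dtype=np.float64))


def read_probability_array(path) -> np.ndarray:
    return np.load(path, allow_pickle=False)["probability"]


def _read_image(path) -> np.ndarray:
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:
        raw = raw[..., :3]
    return raw.astype(np.float64) / 255.0


def load_dataset(image_dir, boxes_csv, masks_dir=None) -> list:
    """Read a dataset laid out as image files + box CSV + optional masks.

    Images carrying a mask get ``fixed_target=True`` with the mask as their
    target (mixed-supervision semantics); callers training box-only variants
    can flip the flag.  An optional ``manifest.json`` next to the CSV may
    carry per-image ``tags`` and ``fixed_target`` overrides.
    """
    image_dir = Path(image_dir)
    boxes = pd.read_csv(boxes_csv)
    required = {"image_id", "x_min", "y_min", "box_w", "box_h"}
    if not required.issubset(boxes.columns):
        raise ValueError(f"boxes CSV must have columns {sorted(required)}")
    manifest = {}
    manifest_path = Path(boxes_csv).parent / "manifest.json"
    if manifest_path.exists():
        manifest = {e["image_id"]: e for e in json.loads(manifest_path.read_text())["images"]}

    images = []
    for image_id, rows in boxes.groupby("image_id", sort=True):
        candidates = sorted(image_dir.glob(f"{image_id}.*"))
        if not candidates:
            raise FileNotFoundError(f"no image file for id {image_id!r} in {image_dir}")
        pixels = _read_image(candidates[0])
        h, w = pixels.shape[:2]
        box_list = []
        for row_idx, row in rows.iterrows():
            if row.box_w <= 0 or row.box_h <= 0:
                raise ValueError(f"boxes CSV row {row_idx}: zero-area box for {image_id}")
            box = BoundingBox.from_corner(row.x_min, row.y_min, row.box_w, row.box_h)
            if not box.intersects_image(w, h):
                raise ValueError(f"boxes CSV row {row_idx}: box outside image {image_id}")
            box_list.append(box)
        gt = None
        if masks_dir is not None:
            mask_candidates = sorted(Path(masks_dir).glob(f"{image_id}.*"))
            if mask_candidates:
                gt = read_mask(mask_candidates[0])
                if gt.shape != (h, w):
                    raise ValueError(f"{image_id}: mask shape {gt.shape} != image {(h, w)}")
        entry = manifest.get(image_id, {})
        fixed = bool(entry.get("fixed_target", gt is not None))
        im = AnnotatedImage(
            image_id=str(image_id),
            pixels=pixels,
            boxes=box_list,
            gt_mask=gt,
            target=gt.copy() if (fixed and gt is not None) else None,
            fixed_target=fixed and gt is not None,
            tags=tuple(entry.get("tags", ())),
        )
        im.validate()
        images.append(im)
    return images


def save_dataset(images: Sequence[AnnotatedImage], out_dir, manifest_extra: Optional[dict] = None) -> None:
    """Write the standard layout: images/, masks/, boxes.csv, manifest.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    entries = []
    for im in images:
        iio.imwrite(out / "images" / f"{im.image_id}.png",
                    np.round(np.clip(im.pixels, 0, 1) * 255).astype(np.uint8))
        if im.gt_mask is not None:
            write_mask(out / "masks" / f"{im.image_id}.png", im.gt_mask)
        for b in im.boxes:
            rows.append({"image_id": im.image_id, "x_min": b.x_min, "y_min": b.y_min,
                         "box_w": b.box_w, "box_h": b.box_h})
        entries.append({"image_id": im.image_id, "fixed_target": im.fixed_target,
                        "tags": list(im.tags)})
    pd.DataFrame(rows).to_csv(out / "boxes.csv", index=False)
    manifest = {"images": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ------------------------------------------------------------ normalization

def compute_dataset_stats(images: Sequence[AnnotatedImage]) -> tuple:
    """Global per-channel mean and std over a set of images."""
    pix = np.concatenate([im.pixels.reshape(-1, 3) for im in images], axis=0)
    return tuple(pix.mean(axis=0)), tuple(pix.std(axis=0))


def normalize_image(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    if cfg.normalization == "per-image":
        mean = image.mean(axis=(0, 1))
        std = image.std(axis=(0, 1))
    else:
        if cfg.dataset_mean is None or cfg.dataset_std is None:
            raise ValueError("dataset-stats normalization needs dataset_mean/dataset_std")
        mean = np.asarray(cfg.dataset_mean)
        std = np.asarray(cfg.dataset_std)
    std = np.where(np.asarray(std) > 0, std, 1.0)
    return (image - mean) / std


# ----------------------------------------------------------- geometric ops

def resize_and_pad(
    image: np.ndarray,
    boxes: Sequence[BoundingBox],
    mask: Optional[np.ndarray],
    cfg: PreprocessConfig,
) -> tuple:
    """Aspect-preserving resize to ``target_size`` on the long side, then
    symmetric zero padding to a square.  Returns ``(image, boxes, mask,
    transform)`` where ``transform`` maps source to output coordinates and
    ``transform.inverse()`` maps back."""
    h, w = image.shape[:2]
    t = GeometricTransform.resize_pad(h, w, cfg.target_size)
    s = cfg.target_size / max(h, w)
    new_h, new_w = round(h * s), round(w * s)
    resized = sk_resize(image, (new_h, new_w), order=1, anti_aliasing=s < 1, preserve_range=True)
    pad_y = (cfg.target_size - new_h) // 2
    pad_x = (cfg.target_size - new_w) // 2
    out = np.zeros((cfg.target_size, cfg.target_size) + image.shape[2:], dtype=image.dtype)
    out[pad_y : pad_y + new_h, pad_x : pad_x + new_w] = resized
    out_mask = None
    if mask is not None:
        rm = sk_resize(mask.astype(float), (new_h, new_w), order=0, anti_aliasing=False, preserve_range=True)
        out_mask = np.zeros((cfg.target_size, cfg.target_size), dtype=np.uint8)
        out_mask[pad_y : pad_y + new_h, pad_x : pad_x + new_w] = (rm > 0.5).astype(np.uint8)
    out_boxes = [transform_box(b, t) for b in boxes]
    return out, out_boxes, out_mask, t


def _integer_shift(arr: np.ndarray, dx: int, dy: int, fill=0) -> np.ndarray:
    out = np.full_like(arr, fill)
    h, w = arr.shape[:2]
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = arr[src_y, src_x]
    return out


def _zoom_arrays(image, mask, factor):
    """Zoom about the image center: rescale then center crop / pad."""
    from skimage.transform import warp, AffineTransform

    h, w = image.shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # output->input mapping for warp
    inv = AffineTransform(scale=(1 / factor, 1 / factor),
                          translation=(cx * (1 - 1 / factor), cy * (1 - 1 / factor)))
    img_out = warp(image, inv, order=1, preserve_range=True)
    mask_out = None
    if mask is not None:
        mask_out = (warp(mask.astype(float), inv, order=0, preserve_range=True) > 0.5).astype(np.uint8)
    return img_out, mask_out


def augment(
    image: np.ndarray,
    boxes: Sequence[BoundingBox],
    mask: Optional[np.ndarray],
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple:
    """Random translation / zoom / mirroring / color shift, with boxes and
    mask co-transformed.  Translations (and zoom-ins) are clamped so no box
    ever leaves the image."""
    if not cfg.enabled:
        return image, list(boxes), mask
    h, w = image.shape[:2]
    boxes = list(boxes)

    # mirroring, probability 1/2 per enabled axis
    if cfg.flip_horizontal and rng.random() < 0.5:
        t = GeometricTransform.hflip(w, h)
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy() if mask is not None else None
        boxes = [transform_box(b, t) for b in boxes]
    if cfg.flip_vertical and rng.random() < 0.5:
        t = GeometricTransform.vflip(w, h)
        image = image[::-1].copy()
        mask = mask[::-1].copy() if mask is not None else None
        boxes = [transform_box(b, t) for b in boxes]

    # zoom in [1 - z, 1 + z]; fall back to identity if a box would leave
    if cfg.zoom_range > 0:
        factor = 1.0 + rng.uniform(-cfg.zoom_range, cfg.zoom_range)
        t = GeometricTransform.zoom(factor, w, h)
        new_boxes = [t.apply_box(b) for b in boxes]
        if all(b.x_min >= -0.5 and b.x_max <= w - 0.5 and b.y_min >= -0.5 and b.y_max <= h - 0.5
               for b in new_boxes):
            image, mask = _zoom_arrays(image, mask, factor)
            boxes = new_boxes

    # integer translation clamped so every box stays fully inside
    if cfg.max_translation > 0 and boxes:
        lo_x = max(-cfg.max_translation, int(np.ceil(max(-0.5 - b.x_min for b in boxes))))
        hi_x = min(cfg.max_translation, int(np.floor(min(w - 0.5 - b.x_max for b in boxes))))
        lo_y = max(-cfg.max_translation, int(np.ceil(max(-0.5 - b.y_min for b in boxes))))
        hi_y = min(cfg.max_translation, int(np.floor(min(h - 0.5 - b.y_max for b in boxes))))
        dx = int(rng.integers(lo_x, hi_x + 1)) if hi_x >= lo_x else 0
        dy = int(rng.integers(lo_y, hi_y + 1)) if hi_y >= lo_y else 0
        if dx or dy:
            t = GeometricTransform.translate(dx, dy, w, h)
            image = _integer_shift(image, dx, dy)
            mask = _integer_shift(mask, dx, dy) if mask is not None else None
            boxes = [transform_box(b, t) for b in boxes]

    # additive per-channel Gaussian color shift (on normalized intensities)
    if cfg.color_shift_std > 0:
        shift = rng.normal(0.0, cfg.color_shift_std, size=3)
        image = image + shift
    return image, boxes, mask
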