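"""Independent scalar-loop oracles used to validate vectorized code.

Everything here is deliberately written as plain double loops over pixels,
straight from the definitions, and shares no code with the package.
"""

import math

import numpy as np


def loss_mask_scalar(center_x, center_y, box_w, box_h, width, height,
                     inner_ring_diameter, outer_ring_diameter, exponent=1.5):
    """Per-pixel re-evaluation of the published ring-mask pseudo-code."""
    inner_radius = min(box_w, box_h) * inner_ring_diameter * 0.5
    outer_radius = max(box_w, box_h) * outer_ring_diameter * 0.5
    if box_w >= box_h:
        x_str, y_str = box_w / box_h, 1.0
    else:
        x_str, y_str = 1.0, box_h / box_w
    dist = [[0.0] * width for _ in range(height)]
    inv = [[0.0] * width for _ in range(height)]
    ramp = [[0.0] * width for _ in range(height)]
    peak = 0.0
    mid = (outer_radius + inner_radius) / 2.0
    for y in range(height):
        for x in range(width):
            d = (x - center_x) ** 2 / x_str + (y - center_y) ** 2 / y_str
            dist[y][x] = d
            if inner_radius < d < outer_radius:
                inv[y][x] = 1.0
                ramp[y][x] = abs(d - mid) ** exponent
                peak = max(peak, ramp[y][x])
    if peak == 0.0:
        raise ValueError("empty ring")
    out = np.empty((height, width))
    for y in range(height):
        for x in range(width):
            out[y, x] = ramp[y][x] / peak + (1.0 - inv[y][x])
    return out


def point_in_box(x, y, center_x, center_y, box_w, box_h):
    return (center_x - box_w / 2.0 <= x < center_x + box_w / 2.0
            and center_y - box_h / 2.0 <= y < center_y + box_h / 2.0)


def clip_scalar(mask, boxes):
    """boxes: list of (center_x, center_y, box_w, box_h) tuples."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if mask[y, x] and any(point_in_box(x, y, *b) for b in boxes):
                out[y, x] = 1
    return out


def circle_count_scalar(center_x, center_y, diameter, width, height):
    r2 = (diameter / 2.0) ** 2
    count = 0
    for y in range(height):
        for x in range(width):
            if (x - center_x) ** 2 + (y - center_y) ** 2 < r2:
                count += 1
    return count


def confusion_scalar(pred, truth):
    tp = tn = fp = fn = 0
    h, w = pred.shape
    for y in range(h):
        for x in range(w):
            p, t = pred[y, x], truth[y, x]
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def dice_scalar(pred, truth):
    tp, tn, fp, fn = confusion_scalar(pred, truth)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def accuracy_scalar(pred, truth):
    tp, tn, fp, fn = confusion_scalar(pred, truth)
    return (tp + tn) / (tp + tn + fp + fn)
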