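"""Box geometry: IoU, minimum enclosing box, GIoU and the GIoU regression loss.

Generalised IoU extends IoU to disjoint boxes: it subtracts from IoU the
fraction of the minimum axis-aligned enclosing box not covered by the union,

    GIoU = IoU - (Ac - U) / Ac,

where U is the union area and Ac the enclosing-box area. GIoU lies in
(-1, 1], equals IoU whenever the enclosing box coincides with the union
region (e.g. nested or identical boxes), and tends to -1 as two boxes of
fixed size separate — so it still ranks configurations that IoU (always 0
when disjoint) and corner-wise L2 distance cannot tell apart. The
regression loss is 1 - GIoU, in [0, 2).

All functions accept either :class:`~endoqa.io_coco.Box` instances or
``(..., 4)`` arrays of ``[x_min, y_min, x_max, y_max]`` and are vectorised
over leading dimensions.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .io_coco import Box

__all__ = ["iou", "giou", "giou_loss", "enclosing_box", "box_area"]


def _as_array(boxes) -> np.ndarray:
    if isinstance(boxes, Box):
        arr = np.array([boxes.x_min, boxes.y_min, boxes.x_max, boxes.y_max], dtype=float)
    elif isinstance(boxes, (list, tuple)) and boxes and isinstance(boxes[0], Box):
        arr = np.array(
            [[b.x_min, b.y_min, b.x_max, b.y_max] for b in boxes], dtype=float
        )
    else:
        arr = np.asarray(boxes, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError(f"expected [x_min, y_min, x_max, y_max] boxes, got shape {arr.shape}")
    widths = arr[..., 2] - arr[..., 0]
    heights = arr[..., 3] - arr[..., 1]
    if np.any(widths <= 0) or np.any(heights <= 0):
        raise ValueError("degenerate (zero or negative area) box")
    return arr


def box_area(boxes) -> np.ndarray | float:
    arr = _as_array(boxes)
    return (arr[..., 2] - arr[..., 0]) * (arr[..., 3] - arr[..., 1])


def _pairwise(a, b) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Intersection, union and enclosing-box areas for element-wise pairs."""
    a = _as_array(a)
    b = _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"box arrays must pair element-wise, got {a.shape} vs {b.shape}")
    ix = np.maximum(
        0.0, np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0])
    )
    iy = np.maximum(
        0.0, np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1])
    )
    inter = ix * iy
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    ex = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
    ey = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
    enclose = ex * ey
    return inter, union, enclose, a


def enclosing_box(a, b) -> np.ndarray:
    """Minimum axis-aligned box enclosing both inputs."""
    a = _as_array(a)
    b = _as_array(b)
    return np.stack(
        [
            np.minimum(a[..., 0], b[..., 0]),
            np.minimum(a[..., 1], b[..., 1]),
            np.maximum(a[..., 2], b[..., 2]),
            np.maximum(a[..., 3], b[..., 3]),
        ],
        axis=-1,
    )


def iou(a, b):
    """Intersection over union; 0 for disjoint boxes."""
    inter, union, _, arr = _pairwise(a, b)
    out = inter / union
    return float(out) if arr.ndim == 1 else out


def giou(a, b):
    """Generalised IoU: ``IoU - (Ac - U) / Ac`` with Ac the enclosing-box area."""
    inter, union, enclose, arr = _pairwise(a, b)
    out = inter / union - (enclose - union) / enclose
    return float(out) if arr.ndim == 1 else out


def iou_matrix(a, b) -> np.ndarray:
    """All-pairs IoU between an (N, 4) and an (M, 4) set."""
    a = _as_array(a)
    b = _as_array(b)
    a = a.reshape(-1, 1, 4)
    b = b.reshape(1, -1, 4)
    ix = np.maximum(
        0.0, np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0])
    )
    iy = np.maximum(
        0.0, np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1])
    )
    inter = ix * iy
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    return inter / (area_a + area_b - inter)


def giou_loss(predicted, target, reduction: str = "mean"):
    """Per-pair regression loss ``1 - GIoU``, reduced by mean or sum.

    Lists must pair element-wise; range is [0, 2) per pair with 0 only for
    a perfect prediction.
    """
    if reduction not in ("mean", "sum", "none"):
        raise ValueError(f"reduction must be mean, sum or none, got {reduction!r}")
    p = _as_array(predicted)
    t = _as_array(target)
    if p.shape != t.shape:
        raise ValueError(f"predicted/target length mismatch: {p.shape} vs {t.shape}")
    losses = 1.0 - np.atleast_1d(giou(p, t))
    if reduction == "mean":
        return float(losses.mean())
    if reduction == "sum":
        return float(losses.sum())
    return losses


def rasterized_giou(a, b, scale: int = 1) -> float:
    """Pixel-counting GIoU oracle for integer-coordinate boxes.

    Rasterises both boxes onto a grid and counts pixels for the
    intersection, union and enclosing box. Exact for integer boxes when
    ``scale`` is 1; intended as an independent cross-check, not for use in
    pipelines.
    """
    a = _as_array(a)
    b = _as_array(b)
    enc = enclosing_box(a, b)
    x0, y0 = int(np.floor(enc[0] * scale)), int(np.floor(enc[1] * scale))
    x1, y1 = int(np.ceil(enc[2] * scale)), int(np.ceil(enc[3] * scale))
    w, h = x1 - x0, y1 - y0
    grid_a = np.zeros((h, w), dtype=bool)
    grid_b = np.zeros((h, w), dtype=bool)
    for arr, grid in ((a, grid_a), (b, grid_b)):
        gx0 = int(round(arr[0] * scale)) - x0
        gy0 = int(round(arr[1] * scale)) - y0
        gx1 = int(round(arr[2] * scale)) - x0
        gy1 = int(round(arr[3] * scale)) - y0
        grid[gy0:gy1, gx0:gx1] = True
    inter = np.count_nonzero(grid_a & grid_b)
    union = np.count_nonzero(grid_a | grid_b)
    enclose = w * h
    return inter / union - (enclose - union) / enclose
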