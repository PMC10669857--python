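"""Effective-area extraction and working-frame standardisation.

Endoscopic frames carry the informative field of view (a bright disk or
rounded rectangle) on a black border that also holds burned-in instrument
and acquisition-time overlays. The effective area is recovered by
thresholding a grayscale version of the frame and applying a morphological
closing, CLOSE(X) = E(D(X)) — dilation followed by erosion with a disk
structuring element — which fills small dark speckles and text gaps; the
largest connected component of the closed mask is taken as the endoscopic
field, discarding overlay fragments. The frame is then cropped to the tight
bounding rectangle of the mask and resized (aspect-distorting) to a square
working size, with the affine transform retained so boxes can be mapped
into and out of working coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, erosion
from skimage.transform import resize

from .io_coco import Box

DEFAULT_THRESHOLD = 15
DEFAULT_RADIUS = 5
DEFAULT_TARGET = 800


@dataclass(frozen=True)
class BoxTransform:
    """Affine map from source to working coordinates: x' = sx*(x - tx)."""

    tx: float
    ty: float
    sx: float
    sy: float

    def apply_point(self, x: float, y: float) -> tuple[float, float]:
        return (self.sx * (x - self.tx), self.sy * (y - self.ty))

    def invert_point(self, x: float, y: float) -> tuple[float, float]:
        return (x / self.sx + self.tx, y / self.sy + self.ty)

    def apply_box(self, box: Box) -> Box:
        x0, y0 = self.apply_point(box.x_min, box.y_min)
        x1, y1 = self.apply_point(box.x_max, box.y_max)
        return replace(box, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def invert_box(self, box: Box) -> Box:
        x0, y0 = self.invert_point(box.x_min, box.y_min)
        x1, y1 = self.invert_point(box.x_max, box.y_max)
        return replace(box, x_min=x0, y_min=y0, x_max=x1, y_max=y1)


@dataclass
class EffectiveAreaMask:
    """Binary mask of informative pixels plus its tight crop rectangle."""

    mask: np.ndarray
    crop_rect: tuple[int, int, int, int]  # x_min, y_min, x_max, y_max (exclusive)
    scale: tuple[float, float] = (1.0, 1.0)

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    # ITU-R 601 luma weights
    return image[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])


def morphological_close(x: np.ndarray, radius: int) -> np.ndarray:
    """CLOSE(X) = E(D(X)) with a disk structuring element, zero background.

    The input is padded before dilation so the closing matches the
    ideal plane-embedded definition (idempotent, extensive) without
    image-border artifacts.
    """
    if radius < 1:
        return x.astype(bool)
    footprint = disk(radius)
    pad = 2 * radius
    padded = np.pad(np.asarray(x, dtype=bool), pad, mode="constant")
    closed = erosion(dilation(padded, footprint), footprint)
    return closed[pad:-pad, pad:-pad].astype(bool)


def effective_area_mask(
    image: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    structuring_radius: int = DEFAULT_RADIUS,
) -> EffectiveAreaMask:
    """Extract the effective imaging area of a frame.

    Thresholds the grayscale frame at ``threshold``, closes the binary
    image with a disk of ``structuring_radius`` pixels, and keeps the
    largest connected component.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    x = gray > threshold
    if not x.any():
        raise ValueError("no effective area: all pixels at or below threshold")
    closed = morphological_close(x, structuring_radius)
    labels = cc_label(closed, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    mask = labels == counts.argmax()
    ys, xs = np.nonzero(mask)
    crop = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return EffectiveAreaMask(mask=mask, crop_rect=crop)


def crop_and_resize(
    image: np.ndarray,
    mask: EffectiveAreaMask,
    target: int = DEFAULT_TARGET,
    crop: bool = True,
) -> tuple[np.ndarray, BoxTransform]:
    """Crop to the mask's bounding rectangle and resize to ``target`` square.

    With ``crop=False`` the frame is masked (non-effective pixels zeroed)
    and resized without cropping. Returns the working image and the
    :class:`BoxTransform` mapping source boxes into working coordinates.
    """
    image = np.asarray(image)
    if image.shape[:2] != mask.mask.shape:
        raise ValueError("mask extent does not match image")
    if crop:
        x0, y0, x1, y1 = mask.crop_rect
    else:
        x0, y0 = 0, 0
        y1, x1 = mask.mask.shape
        m = mask.mask if image.ndim == 2 else mask.mask[..., None]
        image = np.where(m, image, 0)
    if x1 - x0 <= 1 or y1 - y0 <= 1:
        raise ValueError("degenerate crop rectangle")
    window = image[y0:y1, x0:x1]
    sx = target / (x1 - x0)
    sy = target / (y1 - y0)
    if window.shape[:2] == (target, target):
        out = window.copy()
    else:
        out_shape = (target, target) + window.shape[2:]
        out = resize(window, out_shape, preserve_range=True, anti_aliasing=True)
        if np.issubdtype(window.dtype, np.integer):
            out = np.clip(np.rint(out), 0, 255).astype(window.dtype)
    transform = BoxTransform(tx=float(x0), ty=float(y0), sx=sx, sy=sy)
    return out, transform
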