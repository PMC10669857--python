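"""Synthetic endoscopy-like scenes with ground-truthed artifacts.

No public dataset exists for this problem, so the pipeline is exercised on
generated scenes that emulate the structural features of real endoscopic
frames: a bright circular (or rounded-rectangular) effective imaging area
on a black border, a modality-specific palette (reddish white-light,
teal narrow-band, brown iodine staining), eight artifact classes drawn with
the heavy class imbalance of real annotation sets (specularity dominating
at ~47%, instruments below 1%), a controllable fraction of small targets
(< 30 px sides), and an imperfect-detector simulator (box jitter,
confidence noise, misses, class confusion, spurious boxes).

The latent severity of a scene — the fraction of the effective area covered
by artifacts — is recorded so quality scores can be validated against a
known ground-truth ordering. Scenes exist to exercise the geometry,
evaluation and scoring math, not to train clinical models: no tissue
texture, vasculature or photometric realism is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as _resize

from .io_coco import LABELS, Box, Dataset, ImageRecord

#: Class frequencies proportional to real artifact-annotation statistics.
DEFAULT_CLASS_FREQ: dict[str, float] = {
    "blood": 0.0115,
    "blur": 0.0444,
    "bubbles": 0.0808,
    "instrument": 0.0073,
    "specularity": 0.4698,
    "contrast": 0.0933,
    "saturation": 0.0597,
    "artifact": 0.2333,
}

MODALITY_PALETTE: dict[str, tuple[int, int, int]] = {
    "WLI": (185, 110, 95),     # reddish mucosa under white light
    "NBI": (70, 140, 135),     # teal narrow-band tint
    "iodine": (140, 95, 55),   # brown iodine stain
    "unknown": (150, 120, 100),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one generated scene."""

    size: int = 512
    shape: str = "disk"  # or "rounded-rect"
    radius_frac: float = 0.46
    modality: str = "WLI"
    n_artifacts: int | None = None
    area_budget: float | None = None  # target artifact area fraction of effective
    class_freq: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQ)
    )
    small_target_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "rounded-rect"):
            raise ValueError(f"unknown effective-area shape {self.shape!r}")
        if self.area_budget is not None and not 0 <= self.area_budget < 1:
            raise ValueError("area budget must lie in [0, 1)")
        freq_sum = sum(self.class_freq.values())
        if not math.isclose(freq_sum, 1.0, rel_tol=1e-2):
            raise ValueError(f"class frequencies must sum to 1, got {freq_sum}")
        # printed percentage tables carry rounding; renormalise exactly
        object.__setattr__(
            self,
            "class_freq",
            {k: v / freq_sum for k, v in self.class_freq.items()},
        )
        if not 0 <= self.small_target_fraction <= 1:
            raise ValueError("small_target_fraction must lie in [0, 1]")


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    boxes: list[Box]
    spec: SceneSpec | None
    severity: float  # artifact area fraction of the effective area
    effective_mask: np.ndarray | None = None

    @property
    def record(self) -> ImageRecord:
        h, w = self.image.shape[:2]
        modality = self.spec.modality if self.spec else "unknown"
        return ImageRecord(
            image_id=f"scene-{self.spec.seed if self.spec else 0}",
            width=w,
            height=h,
            modality=modality,
        )


def _effective_region(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2
    r = spec.radius_frac * n
    if spec.shape == "disk":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    half = r
    corner = 0.25 * r
    inside_x = np.abs(xx - cx) <= half
    inside_y = np.abs(yy - cy) <= half
    dx = np.maximum(np.abs(xx - cx) - (half - corner), 0)
    dy = np.maximum(np.abs(yy - cy) - (half - corner), 0)
    return inside_x & inside_y & (dx**2 + dy**2 <= corner**2)


def _sample_box(
    label: str,
    mask: np.ndarray,
    rng: np.random.Generator,
    small: bool,
    size: int,
) -> tuple[int, int, int, int] | None:
    """Sample a box of class-typical shape whose center lies in the mask."""
    if small:
        w = int(rng.integers(8, 29))
        h = int(rng.integers(8, 29))
    elif label == "instrument":
        w = int(rng.integers(30, max(size // 3, 31)))
        h = int(rng.integers(60, max(size // 2, 61)))
    elif label in ("blur", "contrast", "saturation"):
        s = int(rng.integers(40, max(size // 3, 41)))
        w, h = s, int(s * rng.uniform(0.7, 1.3))
    else:
        # non-small boxes keep both sides >= 30 px so the small-target
        # fraction is controlled by the spec alone
        w = int(rng.integers(30, max(size // 5, 31)))
        h = int(rng.integers(30, max(size // 5, 31)))
    ys, xs = np.nonzero(mask)
    for _ in range(50):
        i = rng.integers(len(xs))
        cx, cy = xs[i], ys[i]
        x0, y0 = cx - w // 2, cy - h // 2
        x1, y1 = x0 + w, y0 + h
        if 0 <= x0 and 0 <= y0 and x1 <= size and y1 <= size:
            return x0, y0, x1, y1
    return None


def _draw_artifact(
    img: np.ndarray, label: str, rect: tuple[int, int, int, int], rng: np.random.Generator
) -> None:
    x0, y0, x1, y1 = rect
    h, w = y1 - y0, x1 - x0
    patch = img[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[0:h, 0:w]
    radial = ((xx - w / 2) / (w / 2 + 1e-9)) ** 2 + ((yy - h / 2) / (h / 2 + 1e-9)) ** 2
    blob = radial <= 1.0
    if label == "specularity":
        patch[blob] = np.clip(patch[blob] + rng.uniform(200, 255), 0, 255)
    elif label == "bubbles":
        ring = (radial <= 1.0) & (radial >= 0.55)
        patch[ring] = np.clip(patch[ring] + 90, 0, 255)
    elif label == "blur":
        patch = ndi.uniform_filter(patch, size=(max(h // 4, 3), max(w // 4, 3), 1))
    elif label == "contrast":
        mean = patch.mean(axis=(0, 1), keepdims=True)
        patch = mean + 0.25 * (patch - mean)
    elif label == "saturation":
        patch = np.clip(patch * 1.8 + 60, 0, 255)
    elif label == "instrument":
        patch[:, :] = rng.uniform(15, 40, size=3)
    elif label == "blood":
        patch[blob] = [150, 20, 25]
    else:  # generic textured occluder fragment
        texture = rng.uniform(40, 120, size=(h, w, 1)) * np.ones((1, 1, 3))
        patch[blob] = texture[blob]
    img[y0:y1, x0:x1] = np.clip(patch, 0, 255).astype(np.uint8)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one scene: effective region, base tissue tone, artifacts.

    Artifacts are placed until the requested count (``n_artifacts``) or
    effective-area budget (``area_budget``) is met; each primitive gets a
    tight ground-truth box. Identical spec (including seed) reproduces the
    scene bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    mask = _effective_region(spec, rng)
    base = np.array(MODALITY_PALETTE[spec.modality], dtype=float)
    img = np.zeros((n, n, 3), dtype=np.uint8)
    tissue = base[None, None, :] + rng.normal(0, 8, size=(n, n, 3))
    img[mask] = np.clip(tissue[mask], 0, 255).astype(np.uint8)

    labels = list(spec.class_freq)
    probs = np.array([spec.class_freq[k] for k in labels])
    effective_area = float(mask.sum())
    if spec.area_budget is not None and spec.area_budget > 0.8:
        raise ValueError("area budget infeasible within the effective area")

    boxes: list[Box] = []
    covered = 0.0
    max_boxes = spec.n_artifacts if spec.n_artifacts is not None else 200
    attempts = 0
    while True:
        if spec.n_artifacts is not None and len(boxes) >= spec.n_artifacts:
            break
        if spec.area_budget is not None and covered >= spec.area_budget * effective_area:
            break
        if spec.n_artifacts is None and spec.area_budget is None:
            break
        if len(boxes) >= max_boxes or attempts > 500:
            if spec.area_budget is not None and covered < 0.5 * spec.area_budget * effective_area:
                raise ValueError("area budget infeasible within the effective area")
            break
        attempts += 1
        label = labels[rng.choice(len(labels), p=probs)]
        small = rng.random() < spec.small_target_fraction
        rect = _sample_box(label, mask, rng, small, n)
        if rect is None:
            continue
        _draw_artifact(img, label, rect, rng)
        x0, y0, x1, y1 = rect
        boxes.append(Box(float(x0), float(y0), float(x1), float(y1), label=label))
        covered += (x1 - x0) * (y1 - y0)

    severity = covered / effective_area
    return SyntheticScene(
        image=img, boxes=boxes, spec=spec, severity=severity, effective_mask=mask
    )


@dataclass(frozen=True)
class DetectorNoise:
    """Imperfect-detector model applied to ground-truth boxes."""

    jitter_px: float = 0.0
    miss_rate: float = 0.0
    matched_confidence: tuple[float, float] = (1.0, 0.0)  # mean, std
    spurious_rate: float = 0.0  # expected spurious boxes per scene
    spurious_confidence: tuple[float, float] = (0.3, 0.1)
    class_confusion: np.ndarray | None = None  # (8, 8) row-stochastic
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.miss_rate <= 1:
            raise ValueError("miss rate must lie in [0, 1]")
        if self.class_confusion is not None:
            cm = np.asarray(self.class_confusion)
            if cm.shape != (len(LABELS), len(LABELS)) or not np.allclose(
                cm.sum(axis=1), 1.0
            ):
                raise ValueError("class confusion matrix must be 8x8 row-stochastic")

    @classmethod
    def oracle(cls) -> "DetectorNoise":
        return cls()


def simulate_detections(scene: SyntheticScene, noise: DetectorNoise) -> list[Box]:
    """Corrupt the scene's ground truth into detector-like output.

    With the oracle (zero) noise model, detections equal the ground truth
    at confidence 1.0.
    """
    rng = np.random.default_rng(noise.seed)
    h, w = scene.image.shape[:2]
    out: list[Box] = []
    for b in scene.boxes:
        if rng.random() < noise.miss_rate:
            continue
        coords = np.array([b.x_min, b.y_min, b.x_max, b.y_max], dtype=float)
        if noise.jitter_px > 0:
            coords = coords + rng.normal(0, noise.jitter_px, size=4)
        label = b.label
        if noise.class_confusion is not None:
            row = noise.class_confusion[LABELS.index(label)]
            label = LABELS[rng.choice(len(LABELS), p=row)]
        mu, sd = noise.matched_confidence
        conf = float(np.clip(rng.normal(mu, sd) if sd > 0 else mu, 0.0, 1.0))
        candidate = Box(*coords, label=label, confidence=conf).clipped(w, h) if (
            coords[2] > coords[0] and coords[3] > coords[1]
        ) else None
        if candidate is not None:
            out.append(candidate)
    n_spurious = rng.poisson(noise.spurious_rate) if noise.spurious_rate > 0 else 0
    for _ in range(n_spurious):
        bw = rng.integers(10, max(w // 4, 11))
        bh = rng.integers(10, max(h // 4, 11))
        x0 = rng.integers(0, w - bw)
        y0 = rng.integers(0, h - bh)
        mu, sd = noise.spurious_confidence
        conf = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        label = LABELS[rng.integers(len(LABELS))]
        if conf > 0:
            out.append(Box(float(x0), float(y0), float(x0 + bw), float(y0 + bh),
                           label=label, confidence=conf))
    return out


# -- augmentations ------------------------------------------------------------


def mosaic(
    scenes: list[SyntheticScene],
    out_size: int,
    seed: int = 0,
    split: tuple[float, float] | None = None,
    min_survival: float = 0.25,
) -> SyntheticScene:
    """Compose four scenes into one canvas split at a random point.

    Each quadrant receives one input scene resized to the quadrant's
    extent; boxes are transformed accordingly. Boxes whose clipped area
    falls below ``min_survival`` of the original are discarded.
    """
    if len(scenes) != 4:
        raise ValueError(f"mosaic needs exactly 4 scenes, got {len(scenes)}")
    rng = np.random.default_rng(seed)
    if split is None:
        split = (float(rng.uniform(0.3, 0.7)), float(rng.uniform(0.3, 0.7)))
    sx = int(round(split[0] * out_size))
    sy = int(round(split[1] * out_size))
    quads = [
        (0, 0, sx, sy),
        (sx, 0, out_size, sy),
        (0, sy, sx, out_size),
        (sx, sy, out_size, out_size),
    ]
    canvas = np.zeros((out_size, out_size, 3), dtype=np.uint8)
    boxes: list[Box] = []
    for scene, (qx0, qy0, qx1, qy1) in zip(scenes, quads):
        qh, qw = qy1 - qy0, qx1 - qx0
        h, w = scene.image.shape[:2]
        if (h, w) == (qh, qw):
            tile = scene.image
            fx = fy = 1.0
        else:
            tile = np.clip(
                np.rint(_resize(scene.image, (qh, qw, 3), preserve_range=True, anti_aliasing=True)),
                0, 255,
            ).astype(np.uint8)
            fx, fy = qw / w, qh / h
        canvas[qy0:qy1, qx0:qx1] = tile
        for b in scene.boxes:
            nb = replace(
                b,
                x_min=b.x_min * fx + qx0,
                y_min=b.y_min * fy + qy0,
                x_max=b.x_max * fx + qx0,
                y_max=b.y_max * fy + qy0,
            )
            original_area = nb.area
            # content outside the tile belongs to another scene: clip to quadrant
            cx0, cy0 = max(nb.x_min, qx0), max(nb.y_min, qy0)
            cx1, cy1 = min(nb.x_max, qx1), min(nb.y_max, qy1)
            if cx1 - cx0 <= 0 or cy1 - cy0 <= 0:
                continue
            clipped = replace(nb, x_min=cx0, y_min=cy0, x_max=cx1, y_max=cy1)
            if clipped.area < min_survival * original_area:
                continue
            boxes.append(clipped)
    severity = float(np.mean([s.severity for s in scenes]))
    return SyntheticScene(image=canvas, boxes=boxes, spec=None, severity=severity)


def geometric_augment(
    scene: SyntheticScene, op: str, params: dict | None = None
) -> SyntheticScene:
    """Apply a box-consistent geometric transform.

    ``rescale`` (params: factor), ``flip`` (params: axis in horizontal/
    vertical) or ``rotate90`` (params: k quarter-turns clockwise, or
    angle a multiple of 90). Rotations are restricted to right angles so
    boxes remain axis-aligned.
    """
    params = params or {}
    img = scene.image
    h, w = img.shape[:2]
    if op == "rescale":
        factor = float(params.get("factor", 1.0))
        if factor <= 0:
            raise ValueError("rescale factor must be positive")
        nh, nw = int(round(h * factor)), int(round(w * factor))
        out = np.clip(
            np.rint(_resize(img, (nh, nw) + img.shape[2:], preserve_range=True, anti_aliasing=factor < 1)),
            0, 255,
        ).astype(np.uint8)
        boxes = [
            replace(b, x_min=b.x_min * factor, y_min=b.y_min * factor,
                    x_max=b.x_max * factor, y_max=b.y_max * factor)
            for b in scene.boxes
        ]
    elif op == "flip":
        axis = params.get("axis", "horizontal")
        if axis == "horizontal":
            out = img[:, ::-1].copy()
            boxes = [
                replace(b, x_min=w - b.x_max, x_max=w - b.x_min) for b in scene.boxes
            ]
        elif axis == "vertical":
            out = img[::-1].copy()
            boxes = [
                replace(b, y_min=h - b.y_max, y_max=h - b.y_min) for b in scene.boxes
            ]
        else:
            raise ValueError(f"unknown flip axis {axis!r}")
    elif op == "rotate90":
        if "angle" in params:
            angle = params["angle"] % 360
            if angle % 90 != 0:
                raise ValueError(f"rotation angle must be a multiple of 90, got {params['angle']}")
            k = angle // 90
        else:
            k = int(params.get("k", 1)) % 4
        out = img
        boxes = list(scene.boxes)
        for _ in range(k):
            hh, ww = out.shape[:2]
            out = np.rot90(out, k=-1).copy()  # clockwise
            boxes = [
                replace(b, x_min=hh - b.y_max, y_min=b.x_min,
                        x_max=hh - b.y_min, y_max=b.x_max)
                for b in boxes
            ]
    else:
        raise ValueError(f"unknown augmentation {op!r}")
    return SyntheticScene(
        image=out, boxes=boxes, spec=scene.spec, severity=scene.severity
    )


def scene_dataset(
    scenes: list[SyntheticScene],
    detections: list[list[Box]] | None = None,
) -> Dataset:
    """Bundle scenes (and optional detections) into a :class:`Dataset`."""
    images = []
    gt = {}
    det = {}
    for i, scene in enumerate(scenes):
        h, w = scene.image.shape[:2]
        modality = scene.spec.modality if scene.spec else "unknown"
        rec = ImageRecord(image_id=f"scene-{i:04d}", width=w, height=h, modality=modality)
        images.append(rec)
        gt[rec.image_id] = list(scene.boxes)
        if detections is not None:
            det[rec.image_id] = list(detections[i])
    return Dataset(images=images, ground_truth=gt, detections=det)
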