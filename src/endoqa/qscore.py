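"""Detection-driven no-reference quality scoring.

Each detected artifact contributes a penalty built from four multiplicative
weights — its class weight wC, its detector confidence wCo, the fraction wA
of the effective imaging area it covers, and a location weight wL from a
3x3 grid over the frame (central artifacts obstruct reading more than
peripheral ones). The image quality score is

    QS = clamp(1 - sum_B [lambda_A * wC * wCo * wA  +  lambda_L * wC * wCo * wL], 0, 1)

summed over detections B, then mapped linearly onto the 0-5 expert rubric
(5 = pristine, 0 = unreadable). A clean image scores exactly 5; penalties
accumulate monotonically with every additional detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_coco import LABELS, Box, ImageRecord
from .preprocess import EffectiveAreaMask

ZONES = (
    "center",
    "left",
    "right",
    "top",
    "bottom",
    "top-left",
    "top-right",
    "bottom-left",
    "bottom-right",
)

#: Default class weights: the generic occluder class dominates; bubbles,
#: instrument shadows and blood are near-benign for readability.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "artifact": 0.50,
    "specularity": 0.10,
    "saturation": 0.10,
    "blur": 0.20,
    "contrast": 0.10,
    "bubbles": 0.02,
    "instrument": 0.02,
    "blood": 0.02,
}

#: Default location weights over the 3x3 grid.
DEFAULT_LOCATION_WEIGHTS: dict[str, float] = {
    "center": 0.5,
    "left": 0.25,
    "right": 0.25,
    "top": 0.25,
    "bottom": 0.25,
    "top-left": 0.125,
    "top-right": 0.125,
    "bottom-left": 0.125,
    "bottom-right": 0.125,
}


@dataclass(frozen=True)
class WeightConfig:
    """The quality-score parameter set.

    ``lambda_area`` and ``lambda_loc`` balance the area and location terms
    (defaults 0.5 each); ``confidence_floor`` drops detector noise below a
    minimal confidence before scoring.
    """

    class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    location_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_WEIGHTS)
    )
    lambda_area: float = 0.5
    lambda_loc: float = 0.5
    confidence_floor: float = 0.05
    union_area: bool = False

    def __post_init__(self) -> None:
        missing = set(LABELS) - set(self.class_weights)
        if missing:
            raise ValueError(f"class_weights missing labels: {sorted(missing)}")
        missing_zones = set(ZONES) - set(self.location_weights)
        if missing_zones:
            raise ValueError(f"location_weights missing zones: {sorted(missing_zones)}")
        if self.lambda_area < 0 or self.lambda_loc < 0:
            raise ValueError("lambda coefficients must be non-negative")
        if self.lambda_area + self.lambda_loc <= 0:
            raise ValueError("lambda_area + lambda_loc must be positive")
        if not 0 <= self.confidence_floor <= 1:
            raise ValueError("confidence_floor must lie in [0, 1]")

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "WeightConfig":
        kwargs = {}
        if "class_weights" in raw:
            kwargs["class_weights"] = {
                str(k).lower(): float(v) for k, v in raw["class_weights"].items()
            }
        if "location_weights" in raw:
            kwargs["location_weights"] = {
                str(k).lower(): float(v) for k, v in raw["location_weights"].items()
            }
        for key in ("lambda_area", "lambda_loc", "confidence_floor", "union_area"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        return {
            "class_weights": dict(self.class_weights),
            "location_weights": dict(self.location_weights),
            "lambda_area": self.lambda_area,
            "lambda_loc": self.lambda_loc,
            "confidence_floor": self.confidence_floor,
            "union_area": self.union_area,
        }


@dataclass(frozen=True)
class Contribution:
    """Per-detection penalty breakdown."""

    label: str
    w_class: float
    w_confidence: float
    w_area: float
    zone: str
    w_location: float
    penalty: float


@dataclass
class QualityResult:
    image_id: str
    qs_raw: float
    qs_mapped: float
    contributions: list[Contribution]

    @property
    def n_detections(self) -> int:
        return len(self.contributions)

    @property
    def class_area_fractions(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in self.contributions:
            out[c.label] = out.get(c.label, 0.0) + c.w_area
        return out


def location_zone(box: Box, width: float, height: float) -> str:
    """Zone of the 3x3 equal-thirds grid containing the box center."""
    cx, cy = box.center
    if not (0 <= cx <= width and 0 <= cy <= height):
        raise ValueError(f"box center ({cx}, {cy}) outside the {width}x{height} image")
    col = min(int(3 * cx / width), 2)
    row = min(int(3 * cy / height), 2)
    grid = (
        ("top-left", "top", "top-right"),
        ("left", "center", "right"),
        ("bottom-left", "bottom", "bottom-right"),
    )
    return grid[row][col]


def _pixel_coverage(box: Box, mask: np.ndarray) -> float:
    """Exact overlap area between a continuous box and a binary pixel mask.

    Each mask pixel (i, j) occupies the unit cell [j, j+1) x [i, i+1); the
    contribution of a pixel is the area of its cell clipped to the box.
    """
    h, w = mask.shape
    j0 = max(int(np.floor(box.x_min)), 0)
    j1 = min(int(np.ceil(box.x_max)), w)
    i0 = max(int(np.floor(box.y_min)), 0)
    i1 = min(int(np.ceil(box.y_max)), h)
    if j1 <= j0 or i1 <= i0:
        return 0.0
    cols = np.arange(j0, j1)
    rows = np.arange(i0, i1)
    wx = np.minimum(cols + 1.0, box.x_max) - np.maximum(cols, box.x_min)
    wy = np.minimum(rows + 1.0, box.y_max) - np.maximum(rows, box.y_min)
    sub = mask[i0:i1, j0:j1].astype(float)
    return float(wy @ sub @ wx)


def area_weight(box: Box, effective: EffectiveAreaMask | np.ndarray | float) -> float:
    """Fraction of the effective imaging area covered by the box.

    ``effective`` may be an :class:`EffectiveAreaMask`, a raw binary mask,
    or a scalar effective area in px^2 (box then assumed fully inside).
    """
    if isinstance(effective, EffectiveAreaMask):
        mask = effective.mask
    elif isinstance(effective, np.ndarray):
        mask = effective.astype(bool)
    else:
        total = float(effective)
        if total <= 0:
            raise ValueError("effective area must be positive")
        return min(box.area / total, 1.0)
    total = float(np.count_nonzero(mask))
    if total == 0:
        raise ValueError("effective area must be positive")
    return min(_pixel_coverage(box, mask) / total, 1.0)


def quality_score(
    detections: Sequence[Box],
    image: ImageRecord,
    mask: EffectiveAreaMask | np.ndarray | None = None,
    cfg: WeightConfig | None = None,
) -> QualityResult:
    """Score one image from its artifact detections.

    Detections below ``cfg.confidence_floor`` are discarded; each remaining
    detection contributes ``lambda_A*wC*wCo*wA + lambda_L*wC*wCo*wL``. The
    raw score is clamped to [0, 1] and mapped linearly to [0, 5].
    """
    cfg = cfg or WeightConfig()
    effective = mask if mask is not None else float(image.width * image.height)
    if cfg.union_area:
        # overlap between detections counted once: track already-penalised pixels
        if isinstance(effective, EffectiveAreaMask):
            eff_mask = effective.mask.astype(bool)
        elif isinstance(effective, np.ndarray):
            eff_mask = effective.astype(bool)
        else:
            eff_mask = np.ones((image.height, image.width), dtype=bool)
        counted = np.zeros_like(eff_mask)
    contributions: list[Contribution] = []
    for det in detections:
        if det.confidence is None:
            raise ValueError("detections must carry a confidence")
        if det.confidence < cfg.confidence_floor:
            continue
        if det.label not in cfg.class_weights:
            raise ValueError(f"no class weight for label {det.label!r}")
        w_c = float(cfg.class_weights[det.label])
        w_co = float(det.confidence)
        if cfg.union_area:
            total_eff = float(np.count_nonzero(eff_mask))
            if total_eff == 0:
                raise ValueError("effective area must be positive")
            w_a = min(_pixel_coverage(det, eff_mask & ~counted) / total_eff, 1.0)
            i0, i1 = max(int(det.y_min), 0), min(int(np.ceil(det.y_max)), eff_mask.shape[0])
            j0, j1 = max(int(det.x_min), 0), min(int(np.ceil(det.x_max)), eff_mask.shape[1])
            counted[i0:i1, j0:j1] = True
        else:
            w_a = area_weight(det, effective)
        zone = location_zone(det, image.width, image.height)
        w_l = float(cfg.location_weights[zone])
        penalty = cfg.lambda_area * w_c * w_co * w_a + cfg.lambda_loc * w_c * w_co * w_l
        contributions.append(
            Contribution(det.label, w_c, w_co, w_a, zone, w_l, penalty)
        )
    qs_raw = float(np.clip(1.0 - sum(c.penalty for c in contributions), 0.0, 1.0))
    return QualityResult(
        image_id=image.image_id,
        qs_raw=qs_raw,
        qs_mapped=5.0 * qs_raw,
        contributions=contributions,
    )
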