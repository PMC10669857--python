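"""Reading and writing annotations, detections, weight configs and score tables.

Detection data travel as COCO-style JSON (``images`` / ``annotations`` /
``categories`` arrays, boxes as ``[x, y, w, h]``); quality scores and expert
ratings as CSV; weight configurations as YAML. Everything downstream of this
module works with :class:`Box`, :class:`ImageRecord` and :class:`Dataset`
and never touches a file format.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: The closed 8-class artifact vocabulary.
LABELS: tuple[str, ...] = (
    "blood",
    "blur",
    "bubbles",
    "instrument",
    "specularity",
    "contrast",
    "saturation",
    "artifact",
)

#: Common alternative spellings mapped onto the canonical vocabulary.
LABEL_ALIASES: dict[str, str] = {
    "artifacts": "artifact",
    "artefact": "artifact",
    "artefacts": "artifact",
    "specular": "specularity",
    "specular reflection": "specularity",
    "bubble": "bubbles",
    "instruments": "instrument",
    "misc": "artifact",
}


def canonical_label(name: str) -> str:
    """Map a category name onto the 8-class vocabulary (case-insensitive)."""
    key = name.strip().lower()
    key = LABEL_ALIASES.get(key, key)
    if key not in LABELS:
        raise ValueError(
            f"unknown artifact category {name!r}; expected one of {sorted(LABELS)}"
        )
    return key


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in continuous 0-based pixel corner coordinates.

    ``confidence`` is ``None`` for ground-truth boxes and a real in [0, 1]
    for detector output.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box [{self.x_min}, {self.y_min}, {self.x_max}, {self.y_max}]"
            )
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in the 8-class vocabulary")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clipped(self, width: float, height: float) -> "Box | None":
        """Clip to the image extent; ``None`` if nothing with area remains."""
        x0 = min(max(self.x_min, 0.0), width)
        x1 = min(max(self.x_max, 0.0), width)
        y0 = min(max(self.y_min, 0.0), height)
        y1 = min(max(self.y_max, 0.0), height)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def to_coco(self) -> list[float]:
        """Corner coordinates back to COCO ``[x, y, w, h]``."""
        return [self.x_min, self.y_min, self.width, self.height]

    @classmethod
    def from_coco(
        cls, xywh: Iterable[float], label: str, confidence: float | None = None
    ) -> "Box":
        x, y, w, h = (float(v) for v in xywh)
        return cls(x, y, x + w, y + h, label=label, confidence=confidence)


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    width: int
    height: int
    modality: str = "unknown"
    split: str = "unknown"
    path: str | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image extent must be at least 1x1")
        if self.modality not in ("WLI", "NBI", "iodine", "unknown"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class Dataset:
    """Images plus per-image ground-truth and detection boxes."""

    images: list[ImageRecord] = field(default_factory=list)
    ground_truth: dict[str, list[Box]] = field(default_factory=dict)
    detections: dict[str, list[Box]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [im.image_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image_id in dataset")
        known = set(ids)
        for role, mapping in (("ground_truth", self.ground_truth), ("detections", self.detections)):
            unknown = set(mapping) - known
            if unknown:
                raise ValueError(f"{role} refers to unknown image ids: {sorted(unknown)}")

    def image(self, image_id: str) -> ImageRecord:
        for im in self.images:
            if im.image_id == image_id:
                return im
        raise KeyError(image_id)

    @property
    def labels_present(self) -> list[str]:
        out: set[str] = set()
        for boxes in self.ground_truth.values():
            out.update(b.label for b in boxes)
        return sorted(out)


def read_annotations(path: str | Path, role: str = "ground_truth") -> Dataset:
    """Read a COCO-style JSON file into a :class:`Dataset`.

    ``role`` selects whether the annotations populate ``ground_truth`` or
    ``detections``; detections must carry a ``score`` field. Boxes are
    converted from ``[x, y, w, h]`` to corner coordinates, clipped to the
    image extent, and dropped if no area survives clipping.
    """
    if role not in ("ground_truth", "detections"):
        raise ValueError(f"role must be ground_truth or detections, got {role!r}")
    with open(path) as fh:
        payload = json.load(fh)

    categories: dict[int, str] = {}
    for cat in payload.get("categories", []):
        categories[int(cat["id"])] = canonical_label(cat["name"])

    images: list[ImageRecord] = []
    extents: dict[str, tuple[int, int]] = {}
    for im in payload.get("images", []):
        rec = ImageRecord(
            image_id=str(im["id"]),
            width=int(im["width"]),
            height=int(im["height"]),
            modality=im.get("modality", "unknown"),
            split=im.get("split", "unknown"),
            path=im.get("file_name"),
        )
        images.append(rec)
        extents[rec.image_id] = (rec.width, rec.height)

    boxes: dict[str, list[Box]] = {}
    for ann in payload.get("annotations", []):
        image_id = str(ann["image_id"])
        cat_id = int(ann["category_id"])
        if cat_id not in categories:
            raise ValueError(f"annotation refers to unknown category id {cat_id}")
        if role == "detections":
            if "score" not in ann:
                raise ValueError(
                    f"detection on image {image_id!r} is missing a 'score' field"
                )
            conf = float(ann["score"])
        else:
            conf = None
        box = Box.from_coco(ann["bbox"], label=categories[cat_id], confidence=conf)
        if image_id in extents:
            w, h = extents[image_id]
            clipped = box.clipped(w, h)
            if clipped is None:
                continue  # zero-area after clipping: rejected
            box = clipped
        boxes.setdefault(image_id, []).append(box)

    kwargs = {role: boxes}
    return Dataset(images=images, **kwargs)


def write_annotations(dataset: Dataset, path: str | Path, role: str = "ground_truth") -> None:
    """Write one role of a dataset back to COCO-style JSON."""
    mapping = getattr(dataset, role)
    cat_ids = {label: i + 1 for i, label in enumerate(LABELS)}
    payload = {
        "images": [
            {
                "id": im.image_id,
                "width": im.width,
                "height": im.height,
                "modality": im.modality,
                "split": im.split,
                **({"file_name": im.path} if im.path else {}),
            }
            for im in dataset.images
        ],
        "annotations": [],
        "categories": [{"id": i, "name": lbl} for lbl, i in cat_ids.items()],
    }
    ann_id = 1
    for image_id, boxes in mapping.items():
        for b in boxes:
            ann = {
                "id": ann_id,
                "image_id": image_id,
                "category_id": cat_ids[b.label],
                "bbox": b.to_coco(),
                "area": b.area,
            }
            if b.confidence is not None:
                ann["score"] = b.confidence
            payload["annotations"].append(ann)
            ann_id += 1
    with open(path, "w") as fh:
        json.dump(payload, fh)


# -- quality-score and expert-score tables -----------------------------------

SCORE_COLUMNS = ["image_id", "qs_raw", "qs_mapped", "n_detections"]


def write_scores(results, path: str | Path) -> None:
    """Write quality results as CSV (one row per image).

    Columns: image_id, qs_raw, qs_mapped, n_detections, then one
    ``area_frac_<label>`` column per class. Values survive a round trip
    to 6 decimals.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    header = SCORE_COLUMNS + [f"area_frac_{lbl}" for lbl in LABELS]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in results:
            fracs = r.class_area_fractions
            writer.writerow(
                [r.image_id, f"{r.qs_raw:.6f}", f"{r.qs_mapped:.6f}", r.n_detections]
                + [f"{fracs.get(lbl, 0.0):.6f}" for lbl in LABELS]
            )


def read_scores(path: str | Path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(path)


def read_expert_scores(path: str | Path) -> "pd.DataFrame":
    """Read an expert rating table (columns image_id, expert_id, score in 1..5)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"image_id", "expert_id", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"expert score table must have columns {sorted(required)}")
    if not df["score"].between(0, 5).all():
        raise ValueError("expert scores must lie in [0, 5]")
    return df


def read_weight_config(path: str | Path) -> "WeightConfig":
    from .qscore import WeightConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return WeightConfig.from_mapping(raw)


def write_weight_config(cfg: "WeightConfig", path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_mapping(), fh, sort_keys=False)
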