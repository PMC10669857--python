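"""Detection and quality-score evaluation.

Detection side: greedy confidence-descending matching at an IoU threshold,
precision/recall, all-point interpolated average precision (PASCAL VOC 2010
convention), a COCO-style multi-threshold and size-stratified AP report, a
detection confusion matrix with a background row/column, and region-size
distributions. Quality side: Spearman rank correlation with a two-sided
p-value, plus dataset label bookkeeping (per-class counts, ratios, the
imbalance ratio, per-split totals).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import iou_matrix
from .io_coco import LABELS, Box, Dataset

#: COCO size-stratum cutoffs on box area (px^2 on the working frame).
SIZE_BINS = (32**2, 96**2)
#: IoU thresholds for the headline COCO-style AP.
COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 1.0, 0.05), 2))

BACKGROUND = "background"


@dataclass
class MatchResult:
    """TP/FP flags per detection and matched flags per ground truth."""

    det_is_tp: np.ndarray  # bool, ordered by descending confidence
    det_confidence: np.ndarray
    det_matched_gt: np.ndarray  # int index into gt, -1 for FP
    gt_matched: np.ndarray  # bool per ground-truth box
    iou_threshold: float

    @property
    def n_tp(self) -> int:
        return int(self.det_is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.det_is_tp).sum())

    @property
    def n_fn(self) -> int:
        return int((~self.gt_matched).sum())


def match_detections(
    gt: Sequence[Box],
    det: Sequence[Box],
    iou_threshold: float = 0.5,
    same_class: bool = True,
) -> MatchResult:
    """Greedy matching in descending confidence order.

    A detection is a true positive iff its best-IoU still-unmatched ground
    truth (of the same class when ``same_class``) reaches the threshold;
    each ground truth can be claimed once. Unmatched ground truths are
    false negatives.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError(f"IoU threshold {iou_threshold} outside (0, 1]")
    gt = list(gt)
    det = list(det)
    for d in det:
        if d.confidence is None:
            raise ValueError("detections must carry a confidence")
    order = np.argsort([-d.confidence for d in det], kind="stable")
    det_sorted = [det[i] for i in order]
    is_tp = np.zeros(len(det), dtype=bool)
    matched_gt = np.full(len(det), -1, dtype=int)
    gt_matched = np.zeros(len(gt), dtype=bool)
    if gt and det:
        ious = iou_matrix(det_sorted, gt)
    for di, d in enumerate(det_sorted):
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(gt):
            if gt_matched[gi]:
                continue
            if same_class and g.label != d.label:
                continue
            if ious[di, gi] > best_iou:
                best_iou, best_gi = ious[di, gi], gi
        if best_gi >= 0 and best_iou >= iou_threshold:
            is_tp[di] = True
            matched_gt[di] = best_gi
            gt_matched[best_gi] = True
    return MatchResult(
        det_is_tp=is_tp,
        det_confidence=np.array([d.confidence for d in det_sorted], dtype=float),
        det_matched_gt=matched_gt,
        gt_matched=gt_matched,
        iou_threshold=iou_threshold,
    )


@dataclass
class PRCurve:
    """Precision/recall staircase, ordered by descending confidence."""

    recalls: np.ndarray
    precisions: np.ndarray
    confidences: np.ndarray
    n_gt: int

    def __post_init__(self) -> None:
        if len(self.recalls) and np.any(np.diff(self.recalls) < 0):
            raise ValueError("recalls must be nondecreasing")


def pr_curve(
    tp_flags: np.ndarray, confidences: np.ndarray, n_gt: int
) -> PRCurve:
    """Build the PR staircase from per-detection TP flags (dataset-pooled)."""
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    conf = np.asarray(confidences, dtype=float)[order]
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(1.0 - tp)
    recalls = tp_cum / n_gt if n_gt > 0 else np.zeros_like(tp_cum)
    precisions = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    return PRCurve(recalls=recalls, precisions=precisions, confidences=conf, n_gt=n_gt)


def average_precision(pr: PRCurve) -> float:
    """All-point interpolated AP (PASCAL VOC 2010).

    AP = sum_i (r_{i+1} - r_i) * p_interp(r_{i+1}) with
    p_interp(r) = max precision over recalls >= r.
    """
    if len(pr.recalls) == 0 or pr.n_gt == 0:
        return 0.0
    # envelope: running max of precision from the right
    p_interp = np.maximum.accumulate(pr.precisions[::-1])[::-1]
    r = np.concatenate([[0.0], pr.recalls])
    ap = float(np.sum((r[1:] - r[:-1]) * p_interp))
    return ap


def class_ap(
    dataset: Dataset,
    label: str,
    iou_threshold: float = 0.5,
    size_range: tuple[float, float] | None = None,
) -> float | None:
    """AP for one class pooled over the dataset; ``None`` if the class has
    no ground truth (in the requested size stratum)."""
    tp_flags: list[bool] = []
    confs: list[float] = []
    n_gt = 0
    for im in dataset.images:
        gt = [b for b in dataset.ground_truth.get(im.image_id, []) if b.label == label]
        det = [b for b in dataset.detections.get(im.image_id, []) if b.label == label]
        if size_range is not None:
            lo, hi = size_range
            gt = [b for b in gt if lo <= b.area < hi]
            det = [b for b in det if lo <= b.area < hi]
        n_gt += len(gt)
        if det:
            m = match_detections(gt, det, iou_threshold)
            tp_flags.extend(m.det_is_tp.tolist())
            confs.extend(m.det_confidence.tolist())
    if n_gt == 0:
        return None
    return average_precision(pr_curve(np.array(tp_flags), np.array(confs), n_gt))


def ap_report(
    dataset: Dataset,
    thresholds: Sequence[float] = COCO_THRESHOLDS,
    size_bins: tuple[float, float] = SIZE_BINS,
) -> pd.DataFrame:
    """Per-class and mean AP table in COCO convention.

    Columns: AP (mean over ``thresholds``), AP50, AP75, AP_small/medium/
    large (by box area relative to ``size_bins``). Classes absent from the
    ground truth yield NaN and are excluded from the mean row.
    """
    for boxes in dataset.detections.values():
        for b in boxes:
            if b.label not in LABELS:
                raise ValueError(f"unknown class {b.label!r} in detections")
    small, large = size_bins
    strata = {
        "AP_small": (0.0, small),
        "AP_medium": (small, large),
        "AP_large": (large, float("inf")),
    }
    rows = {}
    for label in LABELS:
        aps = [class_ap(dataset, label, t) for t in thresholds]
        valid = [a for a in aps if a is not None]
        row = {
            "AP": float(np.mean(valid)) if valid else np.nan,
            "AP50": _nan(class_ap(dataset, label, 0.50)),
            "AP75": _nan(class_ap(dataset, label, 0.75)),
        }
        for name, rng in strata.items():
            vals = [class_ap(dataset, label, t, size_range=rng) for t in thresholds]
            vals = [v for v in vals if v is not None]
            row[name] = float(np.mean(vals)) if vals else np.nan
        rows[label] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean(skipna=True)
    return table


def _nan(v: float | None) -> float:
    return np.nan if v is None else v


@dataclass
class ConfusionMatrix:
    """Counts over the 8 classes plus a background row/column.

    Cell (true, predicted) counts geometric matches regardless of class;
    unmatched ground truths land in (true, background) and unmatched
    detections in (background, predicted).
    """

    counts: np.ndarray
    labels: tuple[str, ...]

    def normalized(self, axis: str = "row") -> np.ndarray:
        sums = self.counts.sum(axis=1 if axis == "row" else 0, keepdims=True)
        return self.counts / np.maximum(sums, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion(
    dataset: Dataset,
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.5,
) -> ConfusionMatrix:
    """Detection confusion matrix via class-agnostic geometric matching."""
    labels = LABELS + (BACKGROUND,)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for im in dataset.images:
        gt = dataset.ground_truth.get(im.image_id, [])
        det = [
            b
            for b in dataset.detections.get(im.image_id, [])
            if b.confidence >= confidence_threshold
        ]
        m = match_detections(gt, det, iou_threshold, same_class=False)
        order = np.argsort([-d.confidence for d in det], kind="stable")
        det_sorted = [det[i] for i in order]
        for di, d in enumerate(det_sorted):
            gi = m.det_matched_gt[di]
            if gi >= 0:
                counts[idx[gt[gi].label], idx[d.label]] += 1
            else:
                counts[idx[BACKGROUND], idx[d.label]] += 1
        for gi, g in enumerate(gt):
            if not m.gt_matched[gi]:
                counts[idx[g.label], idx[BACKGROUND]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


# -- rank correlation ---------------------------------------------------------


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of the average ranks. The p-value uses
    the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` by default;
    ``method='permutation'`` enumerates all rank permutations exactly
    (only sensible for n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank variance undefined")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(
        np.sum((rx - rx.mean()) * (ry - ry.mean()))
        / math.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    )
    rho = max(-1.0, min(1.0, rho))
    if method == "permutation":
        if n > 8:
            raise ValueError("exact permutation test only supported for n <= 8")
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.sum(rx_c * ry_c[list(perm)])) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


# -- dataset bookkeeping ------------------------------------------------------


@dataclass
class DatasetStats:
    counts: dict[str, int]
    ratios: dict[str, float]  # percent, rounded to 2 decimals
    total: int
    imbalance_ratio: float  # max/min count, rounded to 1 decimal
    split_totals: dict[str, int] = field(default_factory=dict)


def dataset_stats(annotations: Dataset | Mapping[str, int]) -> DatasetStats:
    """Label bookkeeping: per-class counts, percentage ratios, imbalance.

    Accepts either a :class:`Dataset` (counts derived from its ground
    truth, split totals from its image records) or a ready mapping of
    label -> count.
    """
    split_totals: dict[str, int] = {}
    if isinstance(annotations, Dataset):
        counts: dict[str, int] = {}
        for boxes in annotations.ground_truth.values():
            for b in boxes:
                counts[b.label] = counts.get(b.label, 0) + 1
        for im in annotations.images:
            split_totals[im.split] = split_totals.get(im.split, 0) + 1
    else:
        counts = {k: int(v) for k, v in annotations.items()}
    if not counts or sum(counts.values()) == 0:
        raise ValueError("no labels to summarise")
    total = sum(counts.values())
    ratios = {k: round(100.0 * v / total, 2) for k, v in counts.items()}
    nonzero = [v for v in counts.values() if v > 0]
    imbalance = round(max(nonzero) / min(nonzero), 1)
    return DatasetStats(
        counts=counts,
        ratios=ratios,
        total=total,
        imbalance_ratio=imbalance,
        split_totals=split_totals,
    )


def split_totals(table: Mapping[str, Mapping[str, int]]) -> dict[str, int]:
    """Sum a per-modality x per-split image-count table.

    Returns one total per split plus a grand ``total``.
    """
    out: dict[str, int] = {}
    for per_split in table.values():
        for split, n in per_split.items():
            out[split] = out.get(split, 0) + int(n)
    out["total"] = sum(v for k, v in out.items() if k != "total")
    return out


def region_size_distribution(
    boxes: Sequence[Box],
    bins: int | Sequence[float] = 30,
    small_side: float = 30.0,
) -> dict:
    """Histogram of sqrt(box area), plus the small-target tally.

    A box is a small target when both sides are shorter than
    ``small_side`` pixels.
    """
    sizes = np.array([math.sqrt(b.area) for b in boxes], dtype=float)
    hist, edges = np.histogram(sizes, bins=bins) if len(sizes) else (np.array([]), np.array([]))
    n_small = sum(1 for b in boxes if b.width < small_side and b.height < small_side)
    return {
        "sqrt_areas": sizes,
        "hist": hist,
        "bin_edges": edges,
        "n_small": n_small,
        "small_fraction": n_small / len(boxes) if boxes else float("nan"),
    }
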