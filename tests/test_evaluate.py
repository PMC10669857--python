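"""Matching, AP, confusion, Spearman and dataset bookkeeping."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from endoqa.evaluate import (
    average_precision,
    ap_report,
    class_ap,
    confusion,
    dataset_stats,
    match_detections,
    pr_curve,
    region_size_distribution,
    spearman,
    split_totals,
)
from endoqa.io_coco import Box, Dataset, ImageRecord
from endoqa.synthetic import scene_dataset

# Printed per-class label counts of the study dataset.
TABLE2_COUNTS = {
    "blood": 112,
    "blur": 433,
    "bubbles": 788,
    "instrument": 71,
    "specularity": 4582,
    "contrast": 910,
    "saturation": 582,
    "artifact": 2276,
}


def gt_box(x0, y0, x1, y1, label="blur"):
    return Box(x0, y0, x1, y1, label=label)


def det_box(x0, y0, x1, y1, label="blur", conf=1.0):
    return Box(x0, y0, x1, y1, label=label, confidence=conf)


class TestMatchDetections:
    def test_identity_all_tp(self):
        gt = [gt_box(0, 0, 10, 10), gt_box(20, 20, 30, 30)]
        det = [det_box(0, 0, 10, 10), det_box(20, 20, 30, 30)]
        m = match_detections(gt, det, 0.5)
        assert m.n_tp == 2 and m.n_fp == 0 and m.n_fn == 0

    def test_no_detections_all_fn(self):
        gt = [gt_box(0, 0, 10, 10), gt_box(20, 20, 30, 30)]
        m = match_detections(gt, [], 0.5)
        assert m.n_fn == 2 and m.n_tp == 0

    def test_duplicate_detections_greedy_rule(self):
        """Two detections on one gt: the higher-confidence one wins."""
        gt = [gt_box(0, 0, 10, 10)]
        hi = det_box(0, 0, 10, 10, conf=0.9)  # IoU 1.0
        lo = det_box(1, 0, 11, 10, conf=0.8)  # IoU ~0.82
        for det in ([hi, lo], [lo, hi]):  # input order must not matter
            m = match_detections(gt, det, 0.5)
            assert m.n_tp == 1 and m.n_fp == 1
            assert m.det_is_tp[0]  # sorted by confidence: first is the 0.9 one

    def test_class_mismatch_is_fp(self):
        gt = [gt_box(0, 0, 10, 10, label="blur")]
        det = [det_box(0, 0, 10, 10, label="blood")]
        m = match_detections(gt, det, 0.5)
        assert m.n_tp == 0 and m.n_fp == 1 and m.n_fn == 1

    def test_conservation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            gt = [
                gt_box(x, y, x + 10, y + 10)
                for x, y in rng.uniform(0, 80, size=(rng.integers(0, 6), 2))
            ]
            det = [
                det_box(x, y, x + 10, y + 10, conf=float(rng.uniform(0.1, 1)))
                for x, y in rng.uniform(0, 80, size=(rng.integers(0, 6), 2))
            ]
            m = match_detections(gt, det, 0.5)
            assert m.n_tp + m.n_fp == len(det)
            assert m.n_tp + m.n_fn == len(gt)

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            match_detections([], [], iou_threshold=0.0)


def staircase_ap_oracle(tp_pattern, n_gt, grid=200_001):
    """Numeric-integration oracle: p_interp(r) sampled on a dense recall grid."""
    tp_cum = np.cumsum(tp_pattern)
    fp_cum = np.cumsum(1 - np.asarray(tp_pattern))
    recalls = tp_cum / n_gt
    precisions = tp_cum / (tp_cum + fp_cum)
    rs = np.linspace(0, 1, grid)[1:]  # integrate p_interp over (0, 1]
    p_at = np.zeros_like(rs)
    for i, r in enumerate(rs):
        ok = precisions[recalls >= r - 1e-12]
        p_at[i] = ok.max() if len(ok) else 0.0
    return float(np.mean(p_at) * 1.0)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        pr = pr_curve(np.array([1, 1, 1]), np.array([0.9, 0.8, 0.7]), n_gt=3)
        assert average_precision(pr) == pytest.approx(1.0)

    def test_zero_tp(self):
        pr = pr_curve(np.array([0, 0]), np.array([0.9, 0.8]), n_gt=3)
        assert average_precision(pr) == 0.0

    def test_tp_fp_tp_hand_case(self):
        """2 gt, ranked (TP, FP, TP): recall steps at 0.5 and 1.0 with
        interpolated precisions 1 and 2/3 -> AP = 0.5*1 + 0.5*(2/3)."""
        pr = pr_curve(np.array([1, 0, 1]), np.array([0.9, 0.8, 0.7]), n_gt=2)
        assert average_precision(pr) == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-4)

    def test_exhaustive_patterns_vs_staircase_oracle(self):
        """Every TP/FP pattern of up to 6 detections over 2 ground truths."""
        for n in range(1, 7):
            for pattern in itertools.product((0, 1), repeat=n):
                if sum(pattern) > 2:
                    continue  # at most one match per ground truth
                confs = np.linspace(0.9, 0.4, n)
                pr = pr_curve(np.array(pattern), confs, n_gt=2)
                expected = staircase_ap_oracle(pattern, n_gt=2, grid=20_001)
                assert average_precision(pr) == pytest.approx(expected, abs=1e-3), pattern

    def test_invariant_under_monotone_confidence_transform(self):
        rng = np.random.default_rng(6)
        flags = rng.integers(0, 2, size=30)
        confs = np.sort(rng.uniform(0.1, 1, size=30))[::-1]
        ap1 = average_precision(pr_curve(flags, confs, n_gt=int(flags.sum()) + 2))
        ap2 = average_precision(pr_curve(flags, np.sqrt(confs) * 0.5, n_gt=int(flags.sum()) + 2))
        assert ap1 == pytest.approx(ap2)


class TestApReport:
    def test_oracle_detections_reach_ap_one(self, oracle_scenes):
        scenes, dets = oracle_scenes
        ds = scene_dataset(scenes, dets)
        table = ap_report(ds)
        present = table.drop(index="mean").dropna(subset=["AP"])
        assert np.allclose(present["AP"], 1.0)
        assert table.loc["mean", "AP"] == pytest.approx(1.0)

    def test_hopeless_detections_ap_zero(self, oracle_scenes):
        scenes, _ = oracle_scenes
        shifted = [
            [
                Box(b.x_min + 500, b.y_min + 500, b.x_max + 500, b.y_max + 500,
                    label=b.label, confidence=1.0)
                for b in s.boxes
            ]
            for s in scenes
        ]
        ds = scene_dataset(scenes, shifted)
        table = ap_report(ds, thresholds=[0.5])
        assert table.loc["mean", "AP"] == pytest.approx(0.0)

    def test_confident_duplicates_do_not_change_ap50(self, oracle_scenes):
        scenes, dets = oracle_scenes
        ds = scene_dataset(scenes, dets)
        base = ap_report(ds, thresholds=[0.5]).loc["mean", "AP50"]
        doubled = [
            d + [Box(b.x_min, b.y_min, b.x_max, b.y_max, label=b.label, confidence=0.5)
                 for b in d]
            for d in dets
        ]
        ds2 = scene_dataset(scenes, doubled)
        dup = ap_report(ds2, thresholds=[0.5]).loc["mean", "AP50"]
        assert dup == pytest.approx(base)

    def test_unknown_class_rejected(self):
        im = ImageRecord("a", 100, 100)
        bad = Box(0, 0, 10, 10, label="blur", confidence=0.5)
        object.__setattr__(bad, "label", "polyp")
        ds = Dataset(images=[im], ground_truth={"a": []}, detections={"a": [bad]})
        with pytest.raises(ValueError, match="unknown class"):
            ap_report(ds)


class TestConfusion:
    def test_perfect_detections_diagonal(self, oracle_scenes):
        scenes, dets = oracle_scenes
        ds = scene_dataset(scenes, dets)
        cm = confusion(ds, confidence_threshold=0.5)
        off = cm.counts.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    def test_constructed_confusion_single_cell(self):
        im = ImageRecord("a", 100, 100)
        gt = [gt_box(0, 0, 20, 20, label="specularity")]
        det = [det_box(0, 0, 20, 20, label="bubbles", conf=0.9)]
        ds = Dataset(images=[im], ground_truth={"a": gt}, detections={"a": det})
        cm = confusion(ds)
        i_spec = cm.labels.index("specularity")
        i_bub = cm.labels.index("bubbles")
        assert cm.counts[i_spec, i_bub] == 1
        assert cm.counts.sum() == 1

    def test_row_sums_equal_gt_counts(self, oracle_scenes):
        scenes, dets = oracle_scenes
        noisy = [
            d[: max(len(d) - 1, 0)] for d in dets  # drop one detection per scene
        ]
        ds = scene_dataset(scenes, noisy)
        cm = confusion(ds, confidence_threshold=0.0)
        gt_counts = {}
        for boxes in ds.ground_truth.values():
            for b in boxes:
                gt_counts[b.label] = gt_counts.get(b.label, 0) + 1
        for label, count in gt_counts.items():
            i = cm.labels.index(label)
            assert cm.counts[i, :].sum() == count


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 5.0, 9.0]
        rho, p = spearman(x, [v**3 for v in x])
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_perfect_inversion(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_case_no_ties(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)  # 1 - 6*4/(5*24)

    def test_matches_closed_form_on_random_permutations(self):
        rng = np.random.default_rng(10)
        n = 100
        x = np.arange(n, dtype=float)
        for _ in range(100):
            y = rng.permutation(n).astype(float)
            rho, _ = spearman(x, y)
            d2 = np.sum((x + 1 - (y + 1)) ** 2)
            closed = 1 - 6 * d2 / (n * (n**2 - 1))
            assert rho == pytest.approx(closed, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 5, size=40).astype(float)
        y = x + rng.normal(0, 1, size=40)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = spearman(x, y, method="permutation")
        ref = sps.spearmanr(x, y, alternative="two-sided")
        assert rho == pytest.approx(ref.statistic)
        assert 0 < p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDatasetStats:
    def test_printed_counts_total(self):
        stats = dataset_stats(TABLE2_COUNTS)
        assert stats.total == 9754

    def test_printed_counts_ratios(self):
        stats = dataset_stats(TABLE2_COUNTS)
        assert stats.ratios["specularity"] == 46.98
        assert stats.ratios["artifact"] == 23.33
        assert stats.ratios["saturation"] == 5.97
        assert abs(sum(stats.ratios.values()) - 100.0) < 0.05

    def test_imbalance_ratio(self):
        stats = dataset_stats(TABLE2_COUNTS)
        assert stats.imbalance_ratio == 64.5  # 4582 / 71

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no labels"):
            dataset_stats({})

    def test_from_dataset_counts_and_splits(self):
        ims = [
            ImageRecord("a", 10, 10, split="train"),
            ImageRecord("b", 10, 10, split="train"),
            ImageRecord("c", 10, 10, split="test"),
        ]
        gt = {"a": [gt_box(0, 0, 5, 5)], "b": [gt_box(0, 0, 5, 5, label="blood")]}
        stats = dataset_stats(Dataset(images=ims, ground_truth=gt))
        assert stats.counts == {"blur": 1, "blood": 1}
        assert stats.split_totals == {"train": 2, "test": 1}


class TestSplitTotals:
    def test_printed_split_table(self):
        # printed per-modality image counts by split
        table = {
            "WLI": {"train": 738 + 730 + 19, "val": 91 + 90 + 2, "test": 93 + 89 + 4},
            "NBI": {"train": 154 + 150 + 13, "val": 28 + 6 + 4, "test": 27 + 5 + 5},
            "iodine": {"train": 17 + 21 + 0, "val": 4 + 5 + 0, "test": 4 + 4 + 0},
        }
        totals = split_totals(table)
        assert totals["train"] == 1842
        assert totals["total"] == 2303


class TestRegionSizeDistribution:
    def test_sqrt_area(self):
        (box,) = [gt_box(0, 0, 3, 3)]
        out = region_size_distribution([box], bins=[0, 2, 4])
        assert out["sqrt_areas"][0] == pytest.approx(3.0)
        assert out["hist"].tolist() == [0, 1]

    def test_identical_sets_identical_histograms(self, oracle_scenes):
        scenes, dets = oracle_scenes
        gt_all = [b for s in scenes for b in s.boxes]
        det_all = [b for d in dets for b in d]
        bins = np.linspace(0, 200, 21)
        h_gt = region_size_distribution(gt_all, bins=bins)["hist"]
        h_det = region_size_distribution(det_all, bins=bins)["hist"]
        assert np.array_equal(h_gt, h_det)

    def test_small_target_fraction_tracks_generator(self):
        from endoqa.synthetic import SceneSpec, generate_scene

        boxes = []
        i = 0
        while len(boxes) < 500:
            s = generate_scene(SceneSpec(size=256, n_artifacts=10,
                                         small_target_fraction=0.2, seed=500 + i))
            boxes.extend(s.boxes)
            i += 1
        out = region_size_distribution(boxes[:500])
        assert abs(out["small_fraction"] - 0.2) <= 0.05
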