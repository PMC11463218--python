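"""IoU matching, confusion metrics, error statistics and model comparison."""

import itertools
import math

import numpy as np
import pytest

from fishtrack3d.detection_io import TOP, Detection, FrameDetections
from fishtrack3d.evaluation import (
    ComparisonReport,
    ConfusionCounts,
    ErrorStats,
    compare_models,
    error_stats,
    iou,
    match_frame,
    match_stream,
    metrics,
)
from fishtrack3d.reconstruction import Point3D


def _frame(boxes_with_conf):
    dets = tuple(Detection(0, *b, confidence=c) for b, c in boxes_with_conf)
    return FrameDetections(TOP, 0, 0.0, dets)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0.5, 0.5, 0.2, 0.2), (0.5, 0.5, 0.2, 0.2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0.2, 0.2, 0.1, 0.1), (0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_half_overlapping_unit_squares(self):
        # unit squares offset by half a side: inter 0.5, union 1.5
        a = (0.5, 0.5, 1.0, 1.0)
        b = (1.0, 0.5, 1.0, 1.0)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_degenerate_boxes_give_zero(self):
        assert iou((0.5, 0.5, 0.0, 0.0), (0.5, 0.5, 0.0, 0.0)) == 0.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a = tuple(rng.uniform(0.1, 0.9, 2)) + tuple(rng.uniform(0.01, 0.5, 2))
            b = tuple(rng.uniform(0.1, 0.9, 2)) + tuple(rng.uniform(0.01, 0.5, 2))
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0


def _oracle_counts(det_boxes, truth_boxes, iou_thr):
    """Exhaustive matching oracle: maximize matched pairs over all
    injective detection->truth assignments (optimal for small frames)."""
    if not det_boxes and not truth_boxes:
        return ConfusionCounts(tn=1)
    best_tp = 0
    k = min(len(det_boxes), len(truth_boxes))
    for size in range(k, -1, -1):
        for det_sub in itertools.permutations(range(len(det_boxes)), size):
            for truth_sub in itertools.combinations(range(len(truth_boxes)), size):
                tp = sum(
                    iou(det_boxes[d], truth_boxes[t]) >= iou_thr
                    for d, t in zip(det_sub, truth_sub)
                )
                best_tp = max(best_tp, tp)
        if best_tp == size:
            break
    return ConfusionCounts(tp=best_tp, fp=len(det_boxes) - best_tp,
                           fn=len(truth_boxes) - best_tp)


class TestMatchFrame:
    def test_single_match(self):
        truth = [(0.5, 0.5, 0.2, 0.2)]
        frame = _frame([((0.51, 0.5, 0.2, 0.2), 0.95)])
        c = match_frame(frame, truth, iou_threshold=0.5, conf_threshold=0.9)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 0)

    def test_low_confidence_detection_becomes_a_miss(self):
        truth = [(0.5, 0.5, 0.2, 0.2)]
        frame = _frame([((0.5, 0.5, 0.2, 0.2), 0.85)])
        c = match_frame(frame, truth, conf_threshold=0.9)
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_spurious_reflection_counts_as_false_positive(self):
        # the real fish plus a mirrored wall artifact
        truth = [(0.3, 0.5, 0.1, 0.1)]
        frame = _frame([((0.3, 0.5, 0.1, 0.1), 0.95),
                        ((0.05, 0.5, 0.1, 0.1), 0.93)])
        c = match_frame(frame, truth, conf_threshold=0.9)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_empty_frame_with_empty_truth_is_true_negative(self):
        c = match_frame(_frame([]), [])
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 1)

    def test_matches_exhaustive_oracle_in_single_animal_regime(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            n_truth = int(rng.integers(0, 2))  # <=1 truth: greedy is optimal
            n_det = int(rng.integers(0, 4))
            truth = [tuple(rng.uniform(0.2, 0.8, 2)) + (0.2, 0.2)
                     for _ in range(n_truth)]
            dets = [(tuple(rng.uniform(0.2, 0.8, 2)) + (0.2, 0.2), 1.0)
                    for _ in range(n_det)]
            got = match_frame(_frame(dets), truth, iou_threshold=0.5)
            want = _oracle_counts([d[0] for d in dets], truth, 0.5)
            assert got == want

    def test_two_truths_with_clean_assignment(self):
        truth = [(0.2, 0.2, 0.1, 0.1), (0.8, 0.8, 0.1, 0.1)]
        frame = _frame([((0.21, 0.2, 0.1, 0.1), 0.95),
                        ((0.79, 0.8, 0.1, 0.1), 0.92)])
        got = match_frame(frame, truth)
        assert got == _oracle_counts([d.box for d in frame.detections],
                                     truth, 0.5)
        assert got.tp == 2

    def test_stream_accumulation(self):
        frames = [_frame([((0.5, 0.5, 0.2, 0.2), 0.95)]), _frame([])]
        truths = [[(0.5, 0.5, 0.2, 0.2)], []]
        c = match_stream(frames, truths)
        assert (c.tp, c.tn) == (1, 1)


class TestMetrics:
    @pytest.mark.parametrize("tp, fn, acc", [(942, 58, 0.942), (981, 19, 0.981)])
    def test_no_fp_no_tn_pattern(self, tp, fn, acc):
        # the characteristic single-subject pattern: precision 1 and
        # accuracy == recall
        m = metrics(ConfusionCounts(tp=tp, fn=fn))
        assert m.accuracy == pytest.approx(acc)
        assert m.precision == 1.0
        assert m.recall == pytest.approx(acc)

    def test_perfect_detector(self):
        m = metrics(ConfusionCounts(tp=10))
        assert (m.accuracy, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_matches_formula_oracle_on_random_counts(self):
        rng = np.random.default_rng(33)
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 500, 4))
            if tp + fp + tn + fn == 0:
                continue
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            else:
                assert m.precision is None
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))
            else:
                assert m.recall is None
            if fp == 0 and tn == 0 and tp + fn:
                assert m.accuracy == pytest.approx(m.recall)
            if fp == 0 and tp + fp:
                assert m.precision == 1.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())

    def test_undefined_metrics_are_none_not_zero(self):
        m = metrics(ConfusionCounts(tn=5))
        assert m.precision is None and m.recall is None
        assert m.accuracy == 1.0


def _series(coords, start=0):
    return [Point3D(*c, timestamp_s=(start + i) * 0.1, frame_index=start + i)
            for i, c in enumerate(coords)]


class TestErrorStats:
    def test_identical_series(self):
        s = _series([(1, 2, 3), (4, 5, 6)])
        stats = error_stats(s, s)
        assert (stats.max_err_cm, stats.min_err_cm, stats.mean_err_cm) == (0, 0, 0)
        assert stats.n_detected == 2

    def test_three_four_five_offset(self):
        truth = _series([(10, 10, 5)])
        est = _series([(10, 13, 9)])
        stats = error_stats(est, truth)
        assert stats.max_err_cm == stats.min_err_cm == stats.mean_err_cm == 5.0

    def test_restricted_to_common_frames(self):
        truth = _series([(0, 0, 0)] * 10)
        est = _series([(0, 0, 1)] * 4, start=3)
        stats = error_stats(est, truth)
        assert stats.n_detected == 4
        assert stats.mean_err_cm == pytest.approx(1.0)

    def test_no_common_frames_error(self):
        with pytest.raises(ValueError):
            error_stats(_series([(0, 0, 0)]), _series([(0, 0, 0)], start=5))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(17)
        truth = _series(rng.uniform(0, 10, (50, 3)).tolist())
        est = _series(rng.uniform(0, 10, (50, 3)).tolist())
        assert error_stats(est, truth) == error_stats(est[::-1], truth)

    def test_gaussian_offset_mean_matches_chi_expectation(self):
        # mean |N(0, sigma^2 I_3)| = 2 sigma sqrt(2/pi) (chi distribution, k=3)
        rng = np.random.default_rng(100)
        sigma = 0.5
        n = 10_000
        truth_xyz = rng.uniform(5, 35, (n, 3))
        est_xyz = truth_xyz + rng.normal(0, sigma, (n, 3))
        stats = error_stats(_series(est_xyz.tolist()), _series(truth_xyz.tolist()))
        expected = 2 * sigma * math.sqrt(2 / math.pi)
        assert stats.mean_err_cm == pytest.approx(expected, rel=0.10)


class TestCompareModels:
    # the worked comparison: an initial detector finding 1,329 of 3,632
    # frames with errors 0.044..10.892 cm (mean 4.467) against a final one
    # finding all 3,632 with the reported 0.006/0.284/0.428 cm summary
    initial = ErrorStats(n_detected=1329, max_err_cm=10.892,
                         min_err_cm=0.044, mean_err_cm=4.467)
    final = ErrorStats(n_detected=3632, max_err_cm=0.284,
                       min_err_cm=0.006, mean_err_cm=0.428)

    def test_error_range_percent_changes(self):
        report = compare_models(self.initial, self.final).rounded()
        assert report["max_err_pct_change"] == -97.39
        assert report["min_err_pct_change"] == -86.36

    def test_coordinate_count_change_computed_from_inputs(self):
        report = compare_models(self.initial, self.final)
        assert report.coord_pct_change == pytest.approx(
            (3632 - 1329) / 1329 * 100)

    def test_identical_stats_give_zero_everywhere(self):
        report = compare_models(self.final, self.final)
        assert all(v == 0.0 for v in report.as_dict().values())

    def test_zero_initial_stat_is_undefined(self):
        zero = ErrorStats(n_detected=5, max_err_cm=1.0, min_err_cm=0.0,
                          mean_err_cm=0.5)
        report = compare_models(zero, self.final)
        assert report.min_err_pct_change is None

    def test_sign_antisymmetry_for_small_changes(self):
        a = ErrorStats(100, 1.00, 0.10, 0.50)
        b = ErrorStats(100, 1.01, 0.101, 0.505)
        ab = compare_models(a, b)
        ba = compare_models(b, a)
        assert ab.mean_err_pct_change == pytest.approx(
            -ba.mean_err_pct_change, rel=0.05)
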