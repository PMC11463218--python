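"""Detection and coordinate-accuracy evaluation.

Detections are scored against ground-truth boxes by greedy best-IoU
matching after confidence filtering; frame-level tallies feed the usual
confusion metrics

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

For a single always-present animal the only way to earn a true negative is
an empty frame with no detection, so TN (and usually FP) are 0 and accuracy
coincides with recall.  Metrics with a zero denominator are reported as
absent (None), never coerced to 0 or 1.

Coordinate accuracy is summarized as the per-frame Euclidean distance
between an estimated and a reference 3D series, restricted to frames
present in both; two models are compared by signed percent change of each
summary statistic (negative = improvement).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detection_io import Detection, FrameDetections, filter_by_confidence
from .kinematics import euclidean_distance
from .reconstruction import Point3D, Trajectory

DEFAULT_IOU_THRESHOLD = 0.5

Box = tuple[float, float, float, float]  # cx, cy, w, h (normalized)


def _as_box(b) -> Box:
    if isinstance(b, Detection):
        return b.box
    cx, cy, w, h = b
    return float(cx), float(cy), float(w), float(h)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two center-format axis-aligned boxes.

    Returns 0 for disjoint boxes and when both are degenerate (zero area).
    """
    ax, ay, aw, ah = _as_box(box_a)
    bx, by, bw, bh = _as_box(box_b)
    if min(aw, ah, bw, bh) < 0:
        raise ValueError("box extents must be >= 0")
    # corner-based arithmetic throughout so identical boxes give exactly 1
    ax0, ax1 = ax - aw / 2, ax + aw / 2
    ay0, ay1 = ay - ah / 2, ay + ah / 2
    bx0, bx1 = bx - bw / 2, bx + bw / 2
    by0, by1 = by - bh / 2, by + bh / 2
    ix = min(ax1, bx1) - max(ax0, bx0)
    iy = min(ay1, by1) - max(ay0, by0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    if union <= 0:
        return 0.0
    return inter / union


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / precision / recall as fractions; None where undefined."""

    accuracy: float | None
    precision: float | None
    recall: float | None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall}


def match_frame(
    dets: FrameDetections,
    truth_boxes: Sequence[Box],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    conf_threshold: float = 0.0,
) -> ConfusionCounts:
    """Score one frame's detections against its ground-truth boxes.

    Confidence-filtered detections are matched to truth boxes greedily by
    descending IoU, one-to-one.  Matched pairs at IoU >= threshold are TP;
    leftover detections FP; leftover truths FN; an empty-truth,
    empty-detection frame is one TN.  Greedy matching is optimal whenever
    at most one truth box is present — the single-animal regime.
    """
    kept = filter_by_confidence(dets, conf_threshold).detections
    truths = [_as_box(t) for t in truth_boxes]
    if not kept and not truths:
        return ConfusionCounts(tn=1)
    candidates = sorted(
        ((iou(d, t), di, ti) for di, d in enumerate(kept)
         for ti, t in enumerate(truths)),
        key=lambda c: (-c[0], c[1], c[2]),
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for score, di, ti in candidates:
        if score < iou_threshold:
            break
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(kept) - tp, fn=len(truths) - tp)


def match_stream(
    det_frames: Sequence[FrameDetections],
    truth_boxes_per_frame: Sequence[Sequence[Box]],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    conf_threshold: float = 0.0,
) -> ConfusionCounts:
    """Accumulate :func:`match_frame` over an aligned stream."""
    if len(det_frames) != len(truth_boxes_per_frame):
        raise ValueError("detection and truth streams must have equal length")
    total = ConfusionCounts()
    for frame, truths in zip(det_frames, truth_boxes_per_frame):
        total = total + match_frame(frame, truths, iou_threshold, conf_threshold)
    return total


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision and recall from confusion counts.

    A metric whose denominator is zero is reported as None.  All-zero
    counts are an error: there is nothing to evaluate.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall)


# ---------------------------------------------------------------------------
# coordinate error statistics

@dataclass(frozen=True)
class ErrorStats:
    """Euclidean-error summary of an estimated series against a reference.

    Only ``min <= max`` and non-negativity are enforced, so externally
    reported summary triples can be represented verbatim even when their
    own mean falls outside the min..max range.
    """

    n_detected: int
    max_err_cm: float
    min_err_cm: float
    mean_err_cm: float

    def __post_init__(self) -> None:
        if self.n_detected < 1:
            raise ValueError("n_detected must be >= 1")
        if min(self.max_err_cm, self.min_err_cm, self.mean_err_cm) < 0:
            raise ValueError("error statistics must be >= 0")
        if self.min_err_cm > self.max_err_cm:
            raise ValueError("min error exceeds max error")


def _points_by_frame(series) -> dict[int, Point3D]:
    points = series.points if isinstance(series, Trajectory) else series
    out: dict[int, Point3D] = {}
    for p in points:
        if p.frame_index in out:
            raise ValueError(f"duplicate frame_index {p.frame_index}")
        out[p.frame_index] = p
    return out


def error_stats(est, truth) -> ErrorStats:
    """Per-frame Euclidean distances between two 3D series.

    Series are aligned on frame_index; comparison is restricted to frames
    present in both.  ``n_detected`` is the number of matched frames.
    """
    est_by = _points_by_frame(est)
    truth_by = _points_by_frame(truth)
    common = sorted(set(est_by) & set(truth_by))
    if not common:
        raise ValueError("no frames in common between estimate and truth")
    errors = np.array([euclidean_distance(est_by[i], truth_by[i]) for i in common])
    return ErrorStats(
        n_detected=len(common),
        max_err_cm=float(errors.max()),
        min_err_cm=float(errors.min()),
        mean_err_cm=float(errors.mean()),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Signed percent changes from an initial to a final model.

    ``(final - initial) / initial * 100``; negative error changes mean the
    final model improved.  A change whose initial value is zero is None.
    Values keep full precision; ``rounded()`` gives the 2-decimal display
    form.
    """

    coord_pct_change: float | None
    max_err_pct_change: float | None
    min_err_pct_change: float | None
    mean_err_pct_change: float | None

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.as_dict().items()
        }

    def as_dict(self) -> dict:
        return {
            "coord_pct_change": self.coord_pct_change,
            "max_err_pct_change": self.max_err_pct_change,
            "min_err_pct_change": self.min_err_pct_change,
            "mean_err_pct_change": self.mean_err_pct_change,
        }


def _pct_change(initial: float, final: float) -> float | None:
    if initial == 0:
        return None
    return (final - initial) / initial * 100.0


def compare_models(initial: ErrorStats, final: ErrorStats) -> ComparisonReport:
    """Percent-change comparison of two detection/error summaries."""
    return ComparisonReport(
        coord_pct_change=_pct_change(initial.n_detected, final.n_detected),
        max_err_pct_change=_pct_change(initial.max_err_cm, final.max_err_cm),
        min_err_pct_change=_pct_change(initial.min_err_cm, final.min_err_cm),
        mean_err_pct_change=_pct_change(initial.mean_err_cm, final.mean_err_cm),
    )


def write_report_json(
    path: str | Path,
    counts: ConfusionCounts | None = None,
    report: MetricsReport | None = None,
    stats: ErrorStats | None = None,
    comparison: ComparisonReport | None = None,
) -> None:
    """Bundle any subset of evaluation outputs into one JSON report."""
    payload: dict = {}
    if counts is not None:
        payload["confusion"] = {"tp": counts.tp, "fp": counts.fp,
                                "tn": counts.tn, "fn": counts.fn}
    if report is not None:
        payload["metrics"] = report.as_dict()
    if stats is not None:
        payload["error_stats"] = {
            "n_detected": stats.n_detected,
            "max_err_cm": stats.max_err_cm,
            "min_err_cm": stats.min_err_cm,
            "mean_err_cm": stats.mean_err_cm,
        }
    if comparison is not None:
        payload["comparison"] = comparison.rounded()
        payload["comparison_full_precision"] = comparison.as_dict()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
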