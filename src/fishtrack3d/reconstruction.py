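"""Merging the two views into 3D coordinates and assembling trajectories.

The top view supplies (X, Y), the side view (X, Z); the shared X axis is
the merging criterion.  Because both views measure X independently, the
merged X is their arithmetic mean and the absolute disagreement is kept on
every observed point — a disagreement above ``x_tolerance_cm`` marks the
frame as a suspect pairing without discarding it.

Frames where either view contributed no accepted detection leave holes in
the series.  Interior holes no longer than ``max_gap_frames`` are filled by
per-axis linear interpolation between the flanking observations
(provenance ``interpolated``); longer holes, and anything before the first
or after the last observation, are reported as unfilled gaps — the
pipeline never extrapolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection_io import (
    SIDE,
    TOP,
    FrameDetections,
    SynchronizedPair,
    filter_by_confidence,
    select_primary,
)
from .geometry import (
    CameraConfig,
    GeometryConfig,
    OutOfTankError,
    PlanarPoint,
    TankGeometry,
    bbox_center_px,
    px_to_tank,
)

OBSERVED = "observed"
INTERPOLATED = "interpolated"

DEFAULT_X_TOLERANCE_CM = 1.0
DEFAULT_MAX_GAP_FRAMES = 5

TRAJECTORY_CSV_COLUMNS = [
    "frame_index", "timestamp_s", "x_cm", "y_cm", "z_cm",
    "provenance", "x_disagreement_cm",
]


@dataclass(frozen=True)
class Point3D:
    """A physical 3D coordinate with timestamp and provenance."""

    x_cm: float
    y_cm: float
    z_cm: float
    timestamp_s: float
    frame_index: int
    provenance: str = OBSERVED
    x_disagreement_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.provenance not in (OBSERVED, INTERPOLATED):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.timestamp_s < 0:
            raise ValueError("timestamp_s must be >= 0")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x_cm, self.y_cm, self.z_cm)


@dataclass(frozen=True)
class GapRecord:
    """An unfilled run of frames with no 3D coordinate (inclusive bounds)."""

    start_frame: int
    end_frame: int

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class Trajectory:
    """Ordered, uniformly sampled 3D point sequence with its unfilled gaps."""

    points: list[Point3D]
    dt_s: float
    gaps: list[GapRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        tol = 1e-6 * max(1.0, self.dt_s)
        gap_frames = set()
        for g in self.gaps:
            gap_frames.update(range(g.start_frame, g.end_frame + 1))
        prev = None
        for p in self.points:
            if abs(p.timestamp_s - p.frame_index * self.dt_s) > tol + 1e-9:
                raise ValueError(
                    f"frame {p.frame_index}: timestamp {p.timestamp_s} is not "
                    f"frame_index * dt ({p.frame_index * self.dt_s})"
                )
            if prev is not None and p.timestamp_s <= prev:
                raise ValueError("timestamps must be strictly increasing")
            if p.provenance == INTERPOLATED and p.frame_index in gap_frames:
                raise ValueError(
                    f"interpolated point at frame {p.frame_index} lies inside "
                    "a recorded unfilled gap"
                )
            prev = p.timestamp_s

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_observed(self) -> int:
        return sum(p.provenance == OBSERVED for p in self.points)

    @property
    def n_interpolated(self) -> int:
        return sum(p.provenance == INTERPOLATED for p in self.points)

    @property
    def n_gap_frames(self) -> int:
        return sum(g.length for g in self.gaps)

    def coords(self) -> np.ndarray:
        """(n, 3) array of x, y, z in cm."""
        return np.array([[p.x_cm, p.y_cm, p.z_cm] for p in self.points], dtype=float)

    def timestamps(self) -> np.ndarray:
        return np.array([p.timestamp_s for p in self.points], dtype=float)

    def frame_indices(self) -> np.ndarray:
        return np.array([p.frame_index for p in self.points], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.frame_index, p.timestamp_s, p.x_cm, p.y_cm, p.z_cm,
              p.provenance, p.x_disagreement_cm) for p in self.points],
            columns=TRAJECTORY_CSV_COLUMNS,
        )


@dataclass(frozen=True)
class SkippedFrame:
    frame_index: int
    reason: str


@dataclass
class ReconstructionResult:
    """Index-aligned sparse 3D series plus per-frame diagnostics."""

    series: list[Point3D | None]
    frame_indices: list[int]
    dt_s: float
    skipped: list[SkippedFrame] = field(default_factory=list)
    suspect_frames: list[int] = field(default_factory=list)
    single_view: dict[str, list[tuple[int, PlanarPoint]]] = field(
        default_factory=lambda: {TOP: [], SIDE: []}
    )

    @property
    def n_points(self) -> int:
        return sum(p is not None for p in self.series)


def merge_views(
    top_pt: PlanarPoint,
    side_pt: PlanarPoint,
    x_tolerance_cm: float = DEFAULT_X_TOLERANCE_CM,
    frame_index: int = 0,
) -> tuple[Point3D, bool]:
    """Join one top-view and one side-view point into a 3D coordinate.

    Returns ``(point, suspect)`` where ``suspect`` is True when the two
    views' X estimates disagree by more than ``x_tolerance_cm``.
    """
    if top_pt.view != TOP or side_pt.view != SIDE:
        raise ValueError(f"expected (top, side) points, got "
                         f"({top_pt.view!r}, {side_pt.view!r})")
    if abs(top_pt.timestamp_s - side_pt.timestamp_s) > 1e-9:
        raise ValueError(
            f"mismatched timestamps: {top_pt.timestamp_s} vs {side_pt.timestamp_s}"
        )
    disagreement = abs(top_pt.a_cm - side_pt.a_cm)
    point = Point3D(
        x_cm=0.5 * (top_pt.a_cm + side_pt.a_cm),
        y_cm=top_pt.b_cm,
        z_cm=side_pt.b_cm,
        timestamp_s=top_pt.timestamp_s,
        frame_index=frame_index,
        provenance=OBSERVED,
        x_disagreement_cm=disagreement,
    )
    return point, disagreement > x_tolerance_cm


def _frame_to_planar(
    frame: FrameDetections | None,
    cam: CameraConfig,
    tank: TankGeometry,
    conf_threshold: float,
    slack_px: float,
) -> PlanarPoint | None:
    """Reduce one view's frame to a single planar point, or None."""
    if frame is None:
        return None
    det = select_primary(filter_by_confidence(frame, conf_threshold))
    if det is None:
        return None
    p = px_to_tank(bbox_center_px(det, cam), cam, tank,
                   timestamp_s=frame.timestamp_s, slack_px=slack_px)
    return p


def reconstruct_sequence(
    pairs: Sequence[SynchronizedPair],
    top_cam: CameraConfig,
    side_cam: CameraConfig,
    tank: TankGeometry,
    conf_threshold: float = 0.0,
    x_tolerance_cm: float = DEFAULT_X_TOLERANCE_CM,
    slack_px: float = 2.0,
    dt_s: float | None = None,
) -> ReconstructionResult:
    """Run the per-frame pipeline over synchronized pairs.

    Per pair: confidence filter -> primary detection per view -> box center
    -> affine map to the view plane -> two-view merge.  A frame missing an
    accepted detection in either view yields a hole; geometry errors are
    recorded as skipped frames and never abort the run.
    """
    if dt_s is None:
        if len(pairs) >= 2:
            dt_s = pairs[1].timestamp_s - pairs[0].timestamp_s
        else:
            dt_s = 0.1
    result = ReconstructionResult(series=[], frame_indices=[], dt_s=dt_s)
    prev_idx = None
    for pair in pairs:
        if prev_idx is not None and pair.frame_index <= prev_idx:
            raise ValueError("pairs must be sorted by frame_index")
        prev_idx = pair.frame_index
        result.frame_indices.append(pair.frame_index)
        try:
            top_pt = _frame_to_planar(pair.top, top_cam, tank, conf_threshold, slack_px)
            side_pt = _frame_to_planar(pair.side, side_cam, tank, conf_threshold, slack_px)
        except OutOfTankError as exc:
            result.skipped.append(SkippedFrame(pair.frame_index, str(exc)))
            result.series.append(None)
            continue
        if top_pt is not None and side_pt is not None:
            point, suspect = merge_views(top_pt, side_pt, x_tolerance_cm,
                                         frame_index=pair.frame_index)
            result.series.append(point)
            if suspect:
                result.suspect_frames.append(pair.frame_index)
        else:
            result.series.append(None)
            for view, pt in ((TOP, top_pt), (SIDE, side_pt)):
                if pt is not None:
                    result.single_view[view].append((pair.frame_index, pt))
    return result


def fill_gaps(
    series: Sequence[Point3D | None],
    dt_s: float,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    frame_indices: Sequence[int] | None = None,
) -> tuple[list[Point3D | None], list[GapRecord]]:
    """Fill interior holes of length <= ``max_gap_frames`` by linear interpolation.

    Returns the filled (still index-aligned) series and the records of
    every hole left unfilled: holes longer than the cap, and leading or
    trailing holes, which would require extrapolation.
    """
    series = list(series)
    observed_pos = [i for i, p in enumerate(series) if p is not None]
    if not observed_pos:
        raise ValueError("cannot fill gaps in an all-empty series")
    if frame_indices is None:
        # anchor the index axis on the first observation's frame number
        anchor = observed_pos[0]
        first = series[anchor].frame_index - anchor
        frame_indices = list(range(first, first + len(series)))

    unfilled: list[GapRecord] = []
    if observed_pos[0] > 0:
        unfilled.append(GapRecord(frame_indices[0], frame_indices[observed_pos[0] - 1]))
    if observed_pos[-1] < len(series) - 1:
        unfilled.append(GapRecord(frame_indices[observed_pos[-1] + 1], frame_indices[-1]))

    for left, right in zip(observed_pos, observed_pos[1:]):
        run = right - left - 1
        if run == 0:
            continue
        if run > max_gap_frames:
            unfilled.append(GapRecord(frame_indices[left + 1], frame_indices[right - 1]))
            continue
        a, b = series[left], series[right]
        for k in range(1, run + 1):
            frac = k / (run + 1)
            idx = frame_indices[left + k]
            series[left + k] = Point3D(
                x_cm=a.x_cm + frac * (b.x_cm - a.x_cm),
                y_cm=a.y_cm + frac * (b.y_cm - a.y_cm),
                z_cm=a.z_cm + frac * (b.z_cm - a.z_cm),
                timestamp_s=a.timestamp_s + frac * (b.timestamp_s - a.timestamp_s),
                frame_index=idx,
                provenance=INTERPOLATED,
            )
    unfilled.sort(key=lambda g: g.start_frame)
    return series, unfilled


def assemble_trajectory(
    series: Sequence[Point3D | None],
    dt_s: float,
    gaps: Sequence[GapRecord] = (),
) -> Trajectory:
    """Build a validated Trajectory from a (filled) index-aligned series."""
    points = [p for p in series if p is not None]
    if not points:
        raise ValueError("cannot assemble a trajectory from zero points")
    tol = 1e-6 * max(1.0, dt_s)
    for p in points:
        if abs(p.timestamp_s - p.frame_index * dt_s) > tol + 1e-9:
            raise ValueError(
                f"non-uniform timestamp at frame {p.frame_index}: "
                f"{p.timestamp_s} != {p.frame_index * dt_s}"
            )
    return Trajectory(points=points, dt_s=dt_s, gaps=list(gaps))


def reconstruct(
    pairs: Sequence[SynchronizedPair],
    geometry: GeometryConfig,
    conf_threshold: float = 0.0,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    x_tolerance_cm: float = DEFAULT_X_TOLERANCE_CM,
) -> tuple[Trajectory, ReconstructionResult]:
    """Convenience wrapper: pairs -> merged series -> gap fill -> Trajectory."""
    result = reconstruct_sequence(
        pairs, geometry.top, geometry.side, geometry.tank,
        conf_threshold=conf_threshold, x_tolerance_cm=x_tolerance_cm,
        dt_s=geometry.dt_s,
    )
    filled, gaps = fill_gaps(result.series, geometry.dt_s, max_gap_frames,
                             frame_indices=result.frame_indices)
    return assemble_trajectory(filled, geometry.dt_s, gaps), result


# ---------------------------------------------------------------------------
# CSV interfaces

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_trajectory_csv(path: str | Path, dt_s: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    points = [
        Point3D(r.x_cm, r.y_cm, r.z_cm, r.timestamp_s, int(r.frame_index),
                str(r.provenance), float(r.x_disagreement_cm))
        for r in df.itertuples(index=False)
    ]
    if dt_s is None:
        if len(points) >= 2:
            steps = np.diff([p.frame_index for p in points])
            times = np.diff([p.timestamp_s for p in points])
            dt_s = float(np.median(times / steps))
        else:
            dt_s = 0.1
    return Trajectory(points=points, dt_s=round(dt_s, 9))


def write_gap_report_csv(gaps: Sequence[GapRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.start_frame, g.end_frame, g.length) for g in gaps],
        columns=["start_frame", "end_frame", "length"],
    ).to_csv(path, index=False)


def write_ground_truth_csv(traj: Trajectory, path: str | Path) -> None:
    """Ground-truth 3D CSV: frame_index, timestamp_s, x_cm, y_cm, z_cm."""
    df = traj.to_frame()[["frame_index", "timestamp_s", "x_cm", "y_cm", "z_cm"]]
    df.to_csv(path, index=False, float_format="%.6f")


def read_ground_truth_csv(path: str | Path, dt_s: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    needed = {"frame_index", "timestamp_s", "x_cm", "y_cm", "z_cm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    points = [
        Point3D(r.x_cm, r.y_cm, r.z_cm, r.timestamp_s, int(r.frame_index), OBSERVED)
        for r in df.itertuples(index=False)
    ]
    if dt_s is None:
        if len(points) >= 2:
            dt_s = float((points[1].timestamp_s - points[0].timestamp_s)
                         / (points[1].frame_index - points[0].frame_index))
        else:
            dt_s = 0.1
    return Trajectory(points=points, dt_s=round(dt_s, 9))
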