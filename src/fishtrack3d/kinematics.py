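"""Distance and velocity quantities on trajectories.

Instantaneous velocity uses backward differences: the step length from the
previous sample divided by the sampling interval.  Steps that span an
unfilled gap are excluded from the cumulative distance by default rather
than straight-lined, so missing data never fabricates path length; pass
``bridge_gaps=True`` to straight-line across gaps for comparison.
Interpolated points lie on the straight chord between their flanking
observations, so including them adds no artificial length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reconstruction import Point3D, Trajectory

KINEMATICS_CSV_COLUMNS = ["timestamp_s", "velocity_cm_s", "cumulative_cm"]


@dataclass(frozen=True)
class KinematicSample:
    timestamp_s: float
    velocity_cm_s: float
    cumulative_cm: float

    def __post_init__(self) -> None:
        if self.velocity_cm_s < 0 or self.cumulative_cm < 0:
            raise ValueError("velocity and cumulative distance must be >= 0")


def euclidean_distance(p: Point3D, q: Point3D) -> float:
    """Straight-line distance in cm between two 3D points."""
    return math.sqrt(
        (q.x_cm - p.x_cm) ** 2 + (q.y_cm - p.y_cm) ** 2 + (q.z_cm - p.z_cm) ** 2
    )


@dataclass(frozen=True)
class StepSeries:
    """Per-step lengths between consecutive trajectory points.

    ``lengths[i]`` is the step from point ``i`` to point ``i+1``;
    ``included[i]`` is False when that step spans an unfilled gap (the
    points' frame indices are not consecutive).
    """

    lengths: np.ndarray
    included: np.ndarray
    excluded_steps: tuple[tuple[int, int], ...]  # (from_frame, to_frame)

    @property
    def total_cm(self) -> float:
        return float(self.lengths[self.included].sum())


def step_series(traj: Trajectory, bridge_gaps: bool = False) -> StepSeries:
    """Lengths between consecutive points; gap-spanning steps flagged.

    With ``bridge_gaps`` every step is included (straight-line bridging).
    """
    if len(traj) < 2:
        raise ValueError("step_series needs at least 2 points")
    coords = traj.coords()
    lengths = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    frames = traj.frame_indices()
    contiguous = np.diff(frames) == 1
    included = np.ones_like(contiguous) if bridge_gaps else contiguous
    excluded = tuple(
        (int(frames[i]), int(frames[i + 1]))
        for i in np.nonzero(~included)[0]
    )
    return StepSeries(lengths=lengths, included=included, excluded_steps=excluded)


def kinematic_profile(traj: Trajectory, bridge_gaps: bool = False) -> list[KinematicSample]:
    """Per-sample instantaneous velocity and cumulative distance.

    The first sample, and the first sample after an excluded gap-spanning
    step, report velocity 0 (no usable preceding step); cumulative distance
    is the running sum of included steps.
    """
    if len(traj) < 2:
        raise ValueError("kinematic_profile needs at least 2 points")
    steps = step_series(traj, bridge_gaps=bridge_gaps)
    samples = [KinematicSample(traj.points[0].timestamp_s, 0.0, 0.0)]
    cumulative = 0.0
    for i, point in enumerate(traj.points[1:]):
        if steps.included[i]:
            cumulative += float(steps.lengths[i])
            velocity = float(steps.lengths[i]) / traj.dt_s
        else:
            velocity = 0.0
        samples.append(KinematicSample(point.timestamp_s, velocity, cumulative))
    return samples


def total_distance_cm(traj: Trajectory, bridge_gaps: bool = False) -> float:
    return step_series(traj, bridge_gaps=bridge_gaps).total_cm


def write_kinematics_csv(samples: Sequence[KinematicSample], path: str | Path) -> None:
    pd.DataFrame(
        [(s.timestamp_s, s.velocity_cm_s, s.cumulative_cm) for s in samples],
        columns=KINEMATICS_CSV_COLUMNS,
    ).to_csv(path, index=False, float_format="%.6f")
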