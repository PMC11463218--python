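"""Spatial occupancy statistics on a 3 x 3 x 3 partition of the tank.

Each tank axis is split into three equal intervals, giving 27 box-shaped
regions.  Region ids run 1..27 with x varying fastest, then y, then z
bottom-up: ``id = iz*9 + iy*3 + ix + 1``.  Interval membership is half-open
``[lo, hi)`` with the final interval closed, so every point of the closed
tank box is classifiable.  The z layers (iz = 0, 1, 2) are the lower,
middle and upper water-column layers whose totals and percentages
summarize vertical preference — zebrafish strongly favor the surface
layer, so the upper layer typically dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import TankGeometry
from .reconstruction import Point3D

N_PER_AXIS = 3
N_REGIONS = N_PER_AXIS ** 3

DEFAULT_LOW_COLOR = "#00228B"   # dark blue: smallest proportion
DEFAULT_HIGH_COLOR = "#19E04F"  # bright green: largest proportion


def _axis_interval(coord: float, dim: float, slack_cm: float) -> int:
    if coord < -slack_cm or coord > dim + slack_cm:
        raise ValueError(f"coordinate {coord} outside [0, {dim}] beyond slack")
    coord = min(max(coord, 0.0), dim)
    return min(N_PER_AXIS - 1, int(coord * N_PER_AXIS / dim))


def assign_region(p: Point3D, tank: TankGeometry, slack_cm: float = 1e-6) -> int:
    """Region id 1..27 of a point; slack-clamped at the tank boundary."""
    ix = _axis_interval(p.x_cm, tank.length_x_cm, slack_cm)
    iy = _axis_interval(p.y_cm, tank.width_y_cm, slack_cm)
    iz = _axis_interval(p.z_cm, tank.height_z_cm, slack_cm)
    return iz * 9 + iy * 3 + ix + 1


def region_indices(region_id: int) -> tuple[int, int, int]:
    """Inverse of the id formula: (ix, iy, iz), each in 0..2."""
    if not 1 <= region_id <= N_REGIONS:
        raise ValueError(f"region_id must be in 1..{N_REGIONS}")
    r = region_id - 1
    return r % 3, (r // 3) % 3, r // 9


@dataclass(frozen=True)
class RegionGrid:
    """Counts over the 27 regions; ``counts[i]`` belongs to region id i+1."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (N_REGIONS,):
            raise ValueError(f"counts must have shape ({N_REGIONS},)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty grid has no proportions")
        return self.counts / self.total

    def layer_counts(self) -> tuple[int, int, int]:
        """(lower, middle, upper) totals: sums over the 9 regions of each z layer."""
        by_layer = self.counts.reshape(3, 9).sum(axis=1)
        return int(by_layer[0]), int(by_layer[1]), int(by_layer[2])


def region_histogram(points: Iterable[Point3D], tank: TankGeometry,
                     slack_cm: float = 1e-6) -> RegionGrid:
    """Bin points into the 27 regions (order-independent)."""
    counts = np.zeros(N_REGIONS, dtype=int)
    n = 0
    for p in points:
        counts[assign_region(p, tank, slack_cm) - 1] += 1
        n += 1
    if n == 0:
        raise ValueError("region_histogram requires at least one point")
    return RegionGrid(counts)


@dataclass(frozen=True)
class LayerSummary:
    """Totals and percentages for the lower, middle and upper z layers.

    Percentages are computed from the counts and rounded to 2 decimals for
    reporting; full-precision values are available via ``fractions``.
    """

    lower_count: int
    middle_count: int
    upper_count: int

    def __post_init__(self) -> None:
        if min(self.lower_count, self.middle_count, self.upper_count) < 0:
            raise ValueError("layer counts must be non-negative")
        if self.total == 0:
            raise ValueError("layer summary requires at least one point")

    @property
    def total(self) -> int:
        return self.lower_count + self.middle_count + self.upper_count

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        return (self.lower_count / t, self.middle_count / t, self.upper_count / t)

    @property
    def lower_pct(self) -> float:
        return round(100.0 * self.lower_count / self.total, 2)

    @property
    def middle_pct(self) -> float:
        return round(100.0 * self.middle_count / self.total, 2)

    @property
    def upper_pct(self) -> float:
        return round(100.0 * self.upper_count / self.total, 2)


def layer_summary(grid: RegionGrid) -> LayerSummary:
    lower, middle, upper = grid.layer_counts()
    return LayerSummary(lower, middle, upper)


def _hex_to_rgb(color: str) -> tuple[float, float, float]:
    color = color.lstrip("#")
    return tuple(int(color[i:i + 2], 16) / 255.0 for i in (0, 2, 4))


def _rgb_to_hex(rgb: Sequence[float]) -> str:
    return "#" + "".join(f"{round(255 * c):02x}" for c in rgb)


def heatmap_spec(
    grid: RegionGrid,
    tank: TankGeometry,
    max_radius_cm: float | None = None,
    low_color: str = DEFAULT_LOW_COLOR,
    high_color: str = DEFAULT_HIGH_COLOR,
) -> list[dict]:
    """Per-region render records for the occupancy bubble heatmap.

    Each record carries the region's physical cell center, a radius
    linearly proportional to its proportion (the maximum proportion gets
    ``max_radius_cm``, default half the smallest cell dimension), and a
    color linearly interpolated dark-blue -> bright-green over the
    min..max proportion range (uniform grids render mid-ramp).
    """
    props = grid.proportions
    cell = (tank.length_x_cm / 3, tank.width_y_cm / 3, tank.height_z_cm / 3)
    if max_radius_cm is None:
        max_radius_cm = min(cell) / 2
    pmax = float(props.max())
    pmin = float(props.min())
    lo = np.array(_hex_to_rgb(low_color))
    hi = np.array(_hex_to_rgb(high_color))
    records = []
    for region_id in range(1, N_REGIONS + 1):
        ix, iy, iz = region_indices(region_id)
        p = float(props[region_id - 1])
        radius = max_radius_cm * (p / pmax) if pmax > 0 else 0.0
        t = (p - pmin) / (pmax - pmin) if pmax > pmin else 0.5
        records.append({
            "region_id": region_id,
            "ix": ix, "iy": iy, "iz": iz,
            "x_cm": (ix + 0.5) * cell[0],
            "y_cm": (iy + 0.5) * cell[1],
            "z_cm": (iz + 0.5) * cell[2],
            "count": int(grid.counts[region_id - 1]),
            "proportion": p,
            "radius_cm": radius,
            "color": _rgb_to_hex(lo + t * (hi - lo)),
        })
    return records


# ---------------------------------------------------------------------------
# CSV reports

def write_region_csv(grid: RegionGrid, path: str | Path) -> None:
    props = grid.proportions
    rows = []
    for region_id in range(1, N_REGIONS + 1):
        ix, iy, iz = region_indices(region_id)
        rows.append((region_id, ix, iy, iz,
                     int(grid.counts[region_id - 1]), props[region_id - 1]))
    pd.DataFrame(rows, columns=["region_id", "ix", "iy", "iz", "count", "proportion"]
                 ).to_csv(path, index=False, float_format="%.6f")


def write_layer_csv(summary: LayerSummary, path: str | Path) -> None:
    pd.DataFrame(
        [("lower", summary.lower_count, summary.lower_pct),
         ("middle", summary.middle_count, summary.middle_pct),
         ("upper", summary.upper_count, summary.upper_pct)],
        columns=["layer", "count", "percent"],
    ).to_csv(path, index=False)
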