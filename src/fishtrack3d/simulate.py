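"""Synthetic swim simulator: ground-truth trajectories and degraded
two-view detection streams.

The motion model is a bounded correlated random walk at 10 Hz.  Horizontal
heading persists frame-to-frame (parameter ``persistence``), speed is drawn
from a positive distribution around ``mean_speed_cm_s``, and walls reflect.
The vertical coordinate follows a Metropolis random walk whose stationary
density is piecewise-constant over the three water-column layers with
weights ``layer_bias`` — small reflected Gaussian steps plus occasional
burst relocations drawn from the stationary layer distribution itself
(an always-accepted symmetric/independence proposal mixture), so the
long-run layer occupancy converges to ``layer_bias`` exactly while the
path stays mostly smooth.  Zebrafish favor the surface layer, hence the
upper-heavy default bias.

Detector degradation emulates the failure modes of a real box detector on
fish video: per-view Bernoulli dropout (motion blur / missed frames),
Gaussian pixel jitter of the box center, and near-wall reflection false
positives mirrored across the nearest wall in pixel space with mid-range
confidence.  All randomness flows from the single config seed; identical
configs are bit-reproducible.  The detector-confidence model is a labelled
synthetic stand-in: matched detections draw from Beta(20, 1) (mass near 1)
and reflection artifacts from Beta(4, 2), so 0.7/0.9 confidence thresholds
separate them meaningfully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detection_io import SIDE, TOP, Detection, FrameDetections
from .geometry import CameraConfig, GeometryConfig, TankGeometry, tank_to_px
from .reconstruction import OBSERVED, Point3D, Trajectory

Box = tuple[float, float, float, float]

_VIEW_SALT = {TOP: 1, SIDE: 2}


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    ``layer_bias`` is (upper, middle, lower) target occupancy fractions of
    the water column; the default reproduces the strongly surface-biased
    occupancy typical of adult zebrafish in a shallow tank.
    ``fish_size_cm`` is (length, height, width) of the projected body box,
    sized for an adult zebrafish.
    """

    seed: int = 0
    n_frames: int = 600
    dt_s: float = 0.1
    mean_speed_cm_s: float = 6.0
    persistence: float = 0.9
    layer_bias: tuple[float, float, float] = (0.577, 0.177, 0.246)
    fish_size_cm: tuple[float, float, float] = (3.0, 0.7, 0.5)
    dropout_p_top: float = 0.02
    dropout_p_side: float = 0.02
    noise_px_sd: float = 2.0
    reflection_p: float = 0.1
    wall_margin_cm: float = 1.0
    burst_p: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt_s <= 0 or self.mean_speed_cm_s <= 0:
            raise ValueError("dt_s and mean_speed_cm_s must be > 0")
        for name in ("persistence", "dropout_p_top", "dropout_p_side",
                     "reflection_p", "burst_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_px_sd < 0 or self.wall_margin_cm < 0:
            raise ValueError("noise_px_sd and wall_margin_cm must be >= 0")
        if abs(sum(self.layer_bias) - 1.0) > 1e-9 or min(self.layer_bias) < 0:
            raise ValueError("layer_bias must be non-negative and sum to 1")

    def dropout_p(self, view: str) -> float:
        return self.dropout_p_top if view == TOP else self.dropout_p_side

    @property
    def is_clean(self) -> bool:
        """No dropout, no jitter, no reflection artifacts in either view."""
        return (self.dropout_p_top == 0 and self.dropout_p_side == 0
                and self.noise_px_sd == 0 and self.reflection_p == 0)


@dataclass
class SimOutput:
    """Everything one simulated recording session produces."""

    truth: Trajectory
    truth_boxes: dict[str, list[Box]]
    top_stream: list[FrameDetections]
    side_stream: list[FrameDetections]

    def stream(self, view: str) -> list[FrameDetections]:
        return self.top_stream if view == TOP else self.side_stream


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by reflection at the walls."""
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate interval")
    value = (value - lo) % (2 * span)
    if value > span:
        value = 2 * span - value
    return value + lo


def simulate_trajectory(cfg: SimConfig, tank: TankGeometry) -> Trajectory:
    """Generate a bounded correlated-random-walk trajectory in the tank.

    Deterministic under a fixed seed.  With ``persistence == 1`` (and
    ``burst_p == 0``) the heading never turns and the vertical step
    vanishes, so the path is a straight line until the first wall
    reflection.
    """
    if min(tank.length_x_cm, tank.width_y_cm, tank.height_z_cm) <= 0:
        raise ValueError("degenerate tank")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    upper, middle, lower = cfg.layer_bias
    layer_w = np.array([lower, middle, upper])  # indexed bottom -> top
    H = tank.height_z_cm

    turn_sd = math.pi * (1.0 - cfg.persistence)
    z_step_sd = 0.6 * cfg.mean_speed_cm_s * cfg.dt_s * math.sqrt(
        max(0.0, 1.0 - cfg.persistence ** 2))

    # pre-draw every random input so the step loop is pure arithmetic
    turns = rng.normal(0.0, turn_sd, n) if turn_sd > 0 else np.zeros(n)
    speeds = rng.gamma(16.0, cfg.mean_speed_cm_s / 16.0, n)
    u_burst = rng.random(n)
    burst_layers = rng.choice(3, size=n, p=layer_w) if layer_w.min() < 1 else np.zeros(n, int)
    burst_offsets = rng.random(n)
    z_steps = rng.normal(0.0, z_step_sd, n) if z_step_sd > 0 else np.zeros(n)
    u_accept = rng.random(n)

    x = 0.5 * tank.length_x_cm
    y = 0.5 * tank.width_y_cm
    z = (burst_layers[0] + burst_offsets[0]) * H / 3
    theta = 0.0  # initial heading along +x

    def layer_of(zv: float) -> int:
        return min(2, int(zv * 3 / H))

    points = []
    for i in range(n):
        if i > 0:
            theta += turns[i]
            step = speeds[i] * cfg.dt_s
            nx = x + step * math.cos(theta)
            ny = y + step * math.sin(theta)
            # wall reflection flips the matching heading component
            if nx < 0 or nx > tank.length_x_cm:
                theta = math.pi - theta
            if ny < 0 or ny > tank.width_y_cm:
                theta = -theta
            x = _reflect(nx, 0.0, tank.length_x_cm)
            y = _reflect(ny, 0.0, tank.width_y_cm)
            if u_burst[i] < cfg.burst_p:
                # burst relocation: independence proposal from the target
                # layer density, acceptance ratio exactly 1
                z = (burst_layers[i] + burst_offsets[i]) * H / 3
            elif z_step_sd > 0:
                zp = _reflect(z + z_steps[i], 0.0, H)
                ratio = layer_w[layer_of(zp)] / max(layer_w[layer_of(z)], 1e-300)
                if u_accept[i] < ratio:
                    z = zp
        points.append(Point3D(x, y, z, i * cfg.dt_s, i, OBSERVED))
    return Trajectory(points=points, dt_s=cfg.dt_s)


def _clip_box(cx: float, cy: float, w: float, h: float) -> Box:
    """Fit a normalized box inside the unit image.

    Extents shrink symmetrically so the center never moves (preserving the
    round-trip identity near walls); the center itself is clamped only when
    it falls outside the image, e.g. for mirrored reflection artifacts.
    """
    cx = min(max(cx, 0.0), 1.0)
    cy = min(max(cy, 0.0), 1.0)
    w = min(w, 2 * cx, 2 * (1.0 - cx))
    h = min(h, 2 * cy, 2 * (1.0 - cy))
    return cx, cy, w, h


def project_point(
    p: Point3D, cam: CameraConfig, tank: TankGeometry,
    fish_size_cm: tuple[float, float, float],
) -> Box:
    """Ideal normalized detection box of the fish body in one view."""
    length, height, width = fish_size_cm
    if cam.view == TOP:
        a, b = p.x_cm, p.y_cm
        ext_a, ext_b = length, width
    else:
        a, b = p.x_cm, p.z_cm
        ext_a, ext_b = length, height
    u, v = tank_to_px(a, b, cam, tank)
    a_dim, b_dim = tank.planar_dims(cam.view)
    w_px = ext_a / a_dim * cam.roi_w_px
    h_px = ext_b / b_dim * cam.roi_h_px
    return _clip_box(u / cam.image_w_px, v / cam.image_h_px,
                     w_px / cam.image_w_px, h_px / cam.image_h_px)


def project_to_views(
    truth: Trajectory,
    cams: dict[str, CameraConfig],
    tank: TankGeometry,
    fish_size_cm: tuple[float, float, float] = SimConfig.fish_size_cm,
) -> dict[str, list[Box]]:
    """Ideal per-frame truth boxes for both views (inverse of the ROI map)."""
    return {
        view: [project_point(p, cam, tank, fish_size_cm) for p in truth.points]
        for view, cam in cams.items()
    }


def _nearest_wall_mirror(
    box: Box, p: Point3D, cam: CameraConfig, tank: TankGeometry,
) -> tuple[float, float]:
    """Distance (cm) to the nearest wall of the view plane and the mirrored
    normalized center u-coordinate pair (cx, cy) across that wall's ROI edge."""
    a_dim, b_dim = tank.planar_dims(cam.view)
    a = p.x_cm
    b = p.y_cm if cam.view == TOP else p.z_cm
    walls = [  # (distance, edge axis, edge pixel)
        (a, "u", cam.roi[0]),
        (a_dim - a, "u", cam.roi[2]),
        (b, "v", cam.roi[3] if cam.flip_v else cam.roi[1]),
        (b_dim - b, "v", cam.roi[1] if cam.flip_v else cam.roi[3]),
    ]
    dist, axis, edge = min(walls, key=lambda w: w[0])
    cx, cy = box[0], box[1]
    if axis == "u":
        u = cx * cam.image_w_px
        cx = (2 * edge - u) / cam.image_w_px
    else:
        v = cy * cam.image_h_px
        cy = (2 * edge - v) / cam.image_h_px
    return dist, (cx, cy)


def corrupt_stream(
    truth_boxes: Sequence[Box],
    truth: Trajectory,
    cfg: SimConfig,
    view: str,
    cam: CameraConfig,
    tank: TankGeometry,
) -> list[FrameDetections]:
    """Degrade one view's ideal boxes into a realistic detection stream.

    Per frame, independently: with ``dropout_p`` the frame is empty;
    otherwise the center is jittered by ``noise_px_sd`` pixels and given a
    Beta(20, 1) confidence.  When the true position lies within
    ``wall_margin_cm`` of a wall of this view's plane, an extra mirrored
    false positive with Beta(4, 2) confidence is appended with probability
    ``reflection_p``.  In the fully clean limit the stream equals the truth
    boxes with confidence 1.
    """
    if len(truth_boxes) != len(truth.points):
        raise ValueError("truth_boxes and truth must be frame-aligned")
    rng = np.random.default_rng([cfg.seed, _VIEW_SALT[view]])
    clean = cfg.is_clean
    drop_p = cfg.dropout_p(view)
    frames: list[FrameDetections] = []
    for box, p in zip(truth_boxes, truth.points):
        dets: list[Detection] = []
        if not (drop_p > 0 and rng.random() < drop_p):
            cx, cy, w, h = box
            if cfg.noise_px_sd > 0:
                cx += rng.normal(0.0, cfg.noise_px_sd) / cam.image_w_px
                cy += rng.normal(0.0, cfg.noise_px_sd) / cam.image_h_px
            conf = 1.0 if clean else float(rng.beta(20.0, 1.0))
            dets.append(Detection(0, *_clip_box(cx, cy, w, h), confidence=conf))
        if cfg.reflection_p > 0:
            dist, (mx, my) = _nearest_wall_mirror(box, p, cam, tank)
            if dist < cfg.wall_margin_cm and rng.random() < cfg.reflection_p:
                mirrored = _clip_box(mx, my, box[2], box[3])
                dets.append(Detection(0, *mirrored,
                                      confidence=float(rng.beta(4.0, 2.0))))
        frames.append(FrameDetections(view, p.frame_index,
                                      p.timestamp_s, tuple(dets)))
    return frames


def simulate_dataset(cfg: SimConfig, geometry: GeometryConfig) -> SimOutput:
    """Full session: trajectory -> ideal boxes -> degraded two-view streams."""
    cfg = replace(cfg, dt_s=geometry.dt_s)
    truth = simulate_trajectory(cfg, geometry.tank)
    truth_boxes = project_to_views(truth, dict(geometry.cameras),
                                   geometry.tank, cfg.fish_size_cm)
    streams = {
        view: corrupt_stream(truth_boxes[view], truth, cfg, view,
                             geometry.cameras[view], geometry.tank)
        for view in (TOP, SIDE)
    }
    return SimOutput(truth=truth, truth_boxes=truth_boxes,
                     top_stream=streams[TOP], side_stream=streams[SIDE])
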