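"""Pixel <-> physical-coordinate mapping for the two orthogonal camera views.

The tank is a box.  The physical frame has its origin at the viewer's
left-front-bottom corner: X along the tank length (the axis both cameras
share), Y along the width, Z up toward the water surface.  The top camera
images the X-Y plane, the side camera the X-Z plane.

The mapping is a pure affine (proportional) transform from a rectangular
region of interest (ROI) in each image onto the matching physical plane:
lens distortion and perspective are deliberately ignored, and a physical
calibration-board procedure is replaced by the declarative ROI in the
geometry config.  Image rows run downward, so the side view inverts its
vertical axis by default (``flip_v``) to make Z increase toward the
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .detection_io import DEFAULT_DT_S, SIDE, TOP, VIEWS, Detection

#: default pixel slack before a point outside the ROI is an error
DEFAULT_SLACK_PX = 2.0


class OutOfTankError(ValueError):
    """A pixel point fell outside the camera ROI beyond the allowed slack."""

    def __init__(self, message: str, point_px: tuple[float, float]):
        super().__init__(message)
        self.point_px = point_px


@dataclass(frozen=True)
class TankGeometry:
    """Physical dimensions of the box-shaped tank, in cm."""

    length_x_cm: float
    width_y_cm: float
    height_z_cm: float

    def __post_init__(self) -> None:
        for name in ("length_x_cm", "width_y_cm", "height_z_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def planar_dims(self, view: str) -> tuple[float, float]:
        """(a, b) physical extents seen by ``view``: top -> (X, Y), side -> (X, Z)."""
        if view == TOP:
            return self.length_x_cm, self.width_y_cm
        if view == SIDE:
            return self.length_x_cm, self.height_z_cm
        raise ValueError(f"unknown view {view!r}")


def _default_flip(view: str) -> bool:
    # Side view: image rows run downward but Z runs up, so invert by default.
    return view == SIDE


@dataclass(frozen=True)
class CameraConfig:
    """One camera: image size, tank ROI in pixels, and vertical-axis sense."""

    view: str
    image_w_px: int
    image_h_px: int
    roi: tuple[float, float, float, float]  # x0, y0, x1, y1 in pixels
    flip_v: bool | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.image_w_px <= 0 or self.image_h_px <= 0:
            raise ValueError("image dimensions must be positive")
        x0, y0, x1, y1 = self.roi
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate roi {self.roi}")
        if x0 < 0 or y0 < 0 or x1 > self.image_w_px or y1 > self.image_h_px:
            raise ValueError(f"roi {self.roi} outside image "
                             f"{self.image_w_px}x{self.image_h_px}")
        if self.flip_v is None:
            object.__setattr__(self, "flip_v", _default_flip(self.view))
        object.__setattr__(self, "roi", tuple(float(v) for v in self.roi))

    @property
    def roi_w_px(self) -> float:
        return self.roi[2] - self.roi[0]

    @property
    def roi_h_px(self) -> float:
        return self.roi[3] - self.roi[1]


@dataclass(frozen=True)
class PlanarPoint:
    """A physical point in one view's plane: top -> (a=X, b=Y), side -> (a=X, b=Z)."""

    view: str
    a_cm: float
    b_cm: float
    timestamp_s: float = 0.0


def bbox_center_px(det: Detection, cam: CameraConfig) -> tuple[float, float]:
    """De-normalize a detection's box center to full-image pixels."""
    return det.cx * cam.image_w_px, det.cy * cam.image_h_px


def px_to_tank(
    p: tuple[float, float],
    cam: CameraConfig,
    tank: TankGeometry,
    timestamp_s: float = 0.0,
    slack_px: float = DEFAULT_SLACK_PX,
) -> PlanarPoint:
    """Affine-map a full-image pixel point onto the view's physical plane.

    Points up to ``slack_px`` outside the ROI are clamped onto its border;
    farther out raises :class:`OutOfTankError`.
    """
    u, v = p
    x0, y0, x1, y1 = cam.roi
    if u < x0 - slack_px or u > x1 + slack_px or v < y0 - slack_px or v > y1 + slack_px:
        raise OutOfTankError(
            f"pixel ({u:.1f}, {v:.1f}) outside {cam.view} roi {cam.roi} "
            f"beyond {slack_px} px slack",
            (u, v),
        )
    u = min(max(u, x0), x1)
    v = min(max(v, y0), y1)
    a_dim, b_dim = tank.planar_dims(cam.view)
    a_cm = (u - x0) / (x1 - x0) * a_dim
    frac_v = (y1 - v) / (y1 - y0) if cam.flip_v else (v - y0) / (y1 - y0)
    return PlanarPoint(cam.view, a_cm, frac_v * b_dim, timestamp_s)


def tank_to_px(
    a_cm: float,
    b_cm: float,
    cam: CameraConfig,
    tank: TankGeometry,
) -> tuple[float, float]:
    """Exact inverse of :func:`px_to_tank` on the ROI interior."""
    a_dim, b_dim = tank.planar_dims(cam.view)
    x0, y0, x1, y1 = cam.roi
    u = x0 + a_cm / a_dim * (x1 - x0)
    frac_v = b_cm / b_dim
    v = y1 - frac_v * (y1 - y0) if cam.flip_v else y0 + frac_v * (y1 - y0)
    return u, v


def pixel_extent_cm(cam: CameraConfig, tank: TankGeometry) -> tuple[float, float]:
    """Physical size of one pixel after the ROI->tank map (the quantization floor)."""
    a_dim, b_dim = tank.planar_dims(cam.view)
    return a_dim / cam.roi_w_px, b_dim / cam.roi_h_px


# ---------------------------------------------------------------------------
# geometry config file

@dataclass(frozen=True)
class GeometryConfig:
    """Tank + both cameras + sampling interval: everything the pipeline
    needs to place detections in physical space."""

    tank: TankGeometry
    cameras: Mapping[str, CameraConfig] = field(default_factory=dict)
    dt_s: float = DEFAULT_DT_S

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        for view, cam in self.cameras.items():
            if cam.view != view:
                raise ValueError(f"camera keyed {view!r} has view {cam.view!r}")

    @property
    def top(self) -> CameraConfig:
        return self.cameras[TOP]

    @property
    def side(self) -> CameraConfig:
        return self.cameras[SIDE]


def default_geometry() -> GeometryConfig:
    """Bundled example: a 43 x 8 x 14 cm acrylic tank imaged by two 1080p
    cameras, with ROIs whose pixel aspect matches the tank faces."""
    tank = TankGeometry(length_x_cm=43.0, width_y_cm=8.0, height_z_cm=14.0)
    # 1800 px across 43 cm -> 41.9 px/cm in x; y/z ROIs sized to the same scale
    top = CameraConfig(TOP, 1920, 1080, roi=(60.0, 372.0, 1860.0, 707.0))
    side = CameraConfig(SIDE, 1920, 1080, roi=(60.0, 247.0, 1860.0, 833.0))
    return GeometryConfig(tank=tank, cameras={TOP: top, SIDE: side})


def load_geometry(path: str | Path) -> GeometryConfig:
    data = yaml.safe_load(Path(path).read_text())
    try:
        tank = TankGeometry(**{k: float(v) for k, v in data["tank"].items()})
        cameras = {}
        for view, cfg in data["cameras"].items():
            cameras[view] = CameraConfig(
                view=view,
                image_w_px=int(cfg["image_w_px"]),
                image_h_px=int(cfg["image_h_px"]),
                roi=tuple(float(v) for v in cfg["roi"]),
                flip_v=cfg.get("flip_v"),
            )
        return GeometryConfig(tank=tank, cameras=cameras,
                              dt_s=float(data.get("dt_s", DEFAULT_DT_S)))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"bad geometry config {path}: {exc}") from None


def save_geometry(geom: GeometryConfig, path: str | Path) -> None:
    data = {
        "tank": {
            "length_x_cm": geom.tank.length_x_cm,
            "width_y_cm": geom.tank.width_y_cm,
            "height_z_cm": geom.tank.height_z_cm,
        },
        "dt_s": geom.dt_s,
        "cameras": {
            view: {
                "image_w_px": cam.image_w_px,
                "image_h_px": cam.image_h_px,
                "roi": list(cam.roi),
                "flip_v": cam.flip_v,
            }
            for view, cam in geom.cameras.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
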