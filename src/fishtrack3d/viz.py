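"""Dynamic 3D trajectory rendering with recency coloring.

At render time ``t_now``, the trajectory's past points are partitioned by
age into three classes: the most recent second in deep blue, everything
between 1 s and 3 s in light blue, and the older history in gray.  An
optional overlay in the upper-right corner shows the cumulative distance
traveled and the instantaneous velocity at ``t_now``, taken from the
kinematics module so figures and CSV outputs always agree.  Rendering is
side-effect-free on the trajectory data and works headless (Agg backend).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .geometry import TankGeometry  # noqa: E402
from .kinematics import kinematic_profile  # noqa: E402
from .reconstruction import Trajectory  # noqa: E402


@dataclass(frozen=True)
class RenderStyle:
    recent_window_s: float = 1.0
    mid_window_s: float = 3.0
    recent_color: str = "#00339B"  # deep blue
    mid_color: str = "#7EB6FF"    # light blue
    old_color: str = "#9E9E9E"    # gray
    show_overlays: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.recent_window_s < self.mid_window_s:
            raise ValueError("need 0 < recent_window_s < mid_window_s")


def segment_by_recency(
    traj: Trajectory, t_now: float, style: RenderStyle = RenderStyle()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition past point indices into (recent, mid, old) by age.

    recent: age <= recent_window; mid: recent_window < age <= mid_window;
    old: the rest.  Future points (t > t_now) are excluded.  The three
    sets are disjoint and together cover every point with t <= t_now.
    """
    times = traj.timestamps()
    if t_now < times[0] - 1e-9:
        raise ValueError(f"t_now={t_now} precedes the first sample {times[0]}")
    age = t_now - times
    past = age >= -1e-9
    recent = past & (age <= style.recent_window_s + 1e-9)
    mid = past & ~recent & (age <= style.mid_window_s + 1e-9)
    old = past & ~recent & ~mid
    return np.nonzero(recent)[0], np.nonzero(mid)[0], np.nonzero(old)[0]


def render_frame(
    traj: Trajectory,
    t_now: float,
    tank: TankGeometry,
    style: RenderStyle = RenderStyle(),
    out_path: str | Path | None = None,
    ax=None,
) -> dict:
    """Render one snapshot and return its specification.

    The returned dict carries the recency segmentation and the overlay
    values (cumulative distance, instantaneous velocity at ``t_now``)
    regardless of whether a figure was drawn, so callers can test the
    render logic without touching pixels.
    """
    recent, mid, old = segment_by_recency(traj, t_now, style)
    overlay = {"cumulative_cm": 0.0, "velocity_cm_s": 0.0}
    if len(traj) >= 2:
        profile = kinematic_profile(traj)
        current = [s for s in profile if s.timestamp_s <= t_now + 1e-9]
        if current:
            overlay = {"cumulative_cm": current[-1].cumulative_cm,
                       "velocity_cm_s": current[-1].velocity_cm_s}
    spec = {
        "t_now": t_now,
        "segments": {"recent": recent.tolist(), "mid": mid.tolist(),
                     "old": old.tolist()},
        "overlay": overlay,
    }

    if out_path is None and ax is None:
        return spec

    owns_figure = ax is None
    if owns_figure:
        fig = plt.figure(figsize=(8, 6))
        ax = fig.add_subplot(111, projection="3d")
    coords = traj.coords()
    for idx, color, lw in ((old, style.old_color, 0.8),
                           (mid, style.mid_color, 1.2),
                           (recent, style.recent_color, 1.8)):
        if len(idx) > 1:
            ax.plot(coords[idx, 0], coords[idx, 1], coords[idx, 2],
                    color=color, linewidth=lw)
        elif len(idx) == 1:
            ax.scatter(coords[idx, 0], coords[idx, 1], coords[idx, 2],
                       color=color, s=12)
    ax.set_xlim(0, tank.length_x_cm)
    ax.set_ylim(0, tank.width_y_cm)
    ax.set_zlim(0, tank.height_z_cm)
    ax.set_xlabel("X (cm)")
    ax.set_ylabel("Y (cm)")
    ax.set_zlabel("Z (cm)")
    ax.set_box_aspect((tank.length_x_cm, tank.width_y_cm, tank.height_z_cm))
    ax.set_title(f"t = {t_now:.1f} s")
    if style.show_overlays:
        ax.text2D(
            0.98, 0.98,
            f"distance: {overlay['cumulative_cm']:.1f} cm\n"
            f"velocity: {overlay['velocity_cm_s']:.1f} cm/s",
            transform=ax.transAxes, ha="right", va="top", fontsize=9,
        )
    if out_path is not None:
        fig = ax.get_figure()
        fig.savefig(out_path, dpi=110)
    if owns_figure:
        plt.close(ax.get_figure())
    return spec


def render_animation(
    traj: Trajectory,
    tank: TankGeometry,
    out_dir: str | Path,
    times_s: Sequence[float],
    style: RenderStyle = RenderStyle(),
    gif_path: str | Path | None = None,
) -> list[Path]:
    """Render a PNG per requested time; optionally assemble them into a GIF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in times_s:
        path = out_dir / f"frame_t{t:08.1f}s.png"
        render_frame(traj, t, tank, style, out_path=path)
        paths.append(path)
    if gif_path is not None:
        from PIL import Image  # matplotlib dependency, always present

        images = [Image.open(p) for p in paths]
        images[0].save(gif_path, save_all=True, append_images=images[1:],
                       duration=500, loop=0)
    return paths
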