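"""Reading, writing and synchronizing per-camera detection streams.

A detection stream is the time-ordered sequence of bounding-box detections
emitted by an object detector for one camera view.  Two formats are
supported: the darknet/YOLO per-frame text format (``class cx cy w h
[conf]``, coordinates normalized to image size, one file per frame) and a
consolidated per-camera CSV.  Frames are indexed from 0 and time-stamped as
``frame_index * dt_s`` (default 0.1 s, i.e. 10 Hz sampling); file
modification times are never consulted.

Multiple detections in a single-animal frame are legal at this level —
reduction to one box per frame happens only through :func:`select_primary`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

TOP = "top"
SIDE = "side"
VIEWS = (TOP, SIDE)

DEFAULT_DT_S = 0.1

#: tolerance applied before declaring a normalized coordinate out of range
_COORD_TOL = 1e-6

STREAM_CSV_COLUMNS = [
    "camera", "frame_index", "timestamp_s",
    "class_id", "cx", "cy", "w", "h", "confidence",
]


class YoloParseError(ValueError):
    """A YOLO-format line could not be parsed; the message names the line."""


class StreamError(ValueError):
    """A detection stream violates its ordering/uniqueness contract."""


def _check_unit(name: str, value: float) -> float:
    """Clamp ``value`` into [0, 1], tolerating float dust; raise beyond it."""
    if -_COORD_TOL <= value <= 1.0 + _COORD_TOL:
        return min(1.0, max(0.0, value))
    raise ValueError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class Detection:
    """One bounding box with confidence in one camera frame.

    ``cx, cy`` are the box center and ``w, h`` the box extents, all as
    fractions of the image size.  ``confidence`` defaults to 1.0, the
    convention for ground-truth-style 5-field annotation lines.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h", "confidence"):
            object.__setattr__(self, name, _check_unit(name, getattr(self, name)))
        if self.class_id < 0:
            raise ValueError(f"class_id must be non-negative, got {self.class_id}")

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.cx, self.cy, self.w, self.h)


@dataclass(frozen=True)
class FrameDetections:
    """All detections of one camera frame (possibly none: a missed frame)."""

    camera: str
    frame_index: int
    timestamp_s: float
    detections: tuple[Detection, ...] = ()

    def __post_init__(self) -> None:
        if self.camera not in VIEWS:
            raise ValueError(f"camera must be one of {VIEWS}, got {self.camera!r}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "detections", tuple(self.detections))

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def is_empty(self) -> bool:
        return not self.detections


@dataclass(frozen=True)
class SynchronizedPair:
    """The two views of one time point; either side may be absent."""

    frame_index: int
    timestamp_s: float
    top: FrameDetections | None = None
    side: FrameDetections | None = None

    def __post_init__(self) -> None:
        for frame in (self.top, self.side):
            if frame is not None and frame.frame_index != self.frame_index:
                raise ValueError(
                    f"pair frame_index {self.frame_index} != "
                    f"{frame.camera} frame_index {frame.frame_index}"
                )


def parse_yolo_frame(
    text: str,
    camera: str,
    frame_index: int,
    dt_s: float = DEFAULT_DT_S,
) -> FrameDetections:
    """Parse the content of one YOLO txt annotation file.

    Each non-empty line is ``class cx cy w h`` or ``class cx cy w h conf``;
    an empty file is a legal missed frame.  Malformed lines raise
    :class:`YoloParseError` naming the 1-based line number.
    """
    detections: list[Detection] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise YoloParseError(
                f"line {lineno}: expected 5 or 6 fields, got {len(parts)}"
            )
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise YoloParseError(f"line {lineno}: non-numeric field ({exc})") from None
        if values[0] != int(values[0]):
            raise YoloParseError(f"line {lineno}: class id {parts[0]} is not an integer")
        conf = values[5] if len(values) == 6 else 1.0
        try:
            det = Detection(int(values[0]), *values[1:5], confidence=conf)
        except ValueError as exc:
            raise YoloParseError(f"line {lineno}: {exc}") from None
        detections.append(det)
    return FrameDetections(camera, frame_index, frame_index * dt_s, tuple(detections))


def format_yolo_frame(frame: FrameDetections, decimals: int = 6) -> str:
    """Serialize a frame back to YOLO txt (inverse of :func:`parse_yolo_frame`)."""
    fmt = f"{{:.{decimals}f}}"
    lines = []
    for d in frame.detections:
        fields = [str(d.class_id)] + [fmt.format(v) for v in (d.cx, d.cy, d.w, d.h, d.confidence)]
        lines.append(" ".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def filter_by_confidence(frame: FrameDetections, threshold: float) -> FrameDetections:
    """Keep detections with confidence >= ``threshold`` (inclusive), preserving order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept = tuple(d for d in frame.detections if d.confidence >= threshold)
    return replace(frame, detections=kept)


def select_primary(frame: FrameDetections) -> Detection | None:
    """The highest-confidence detection; earlier line wins ties; None if empty.

    Single-animal plumbing: downstream reconstruction expects at most one
    subject per frame, so a frame's detections are reduced to the most
    confident box.
    """
    if frame.is_empty:
        return None
    return max(frame.detections, key=lambda d: d.confidence)


def pair_streams(
    top: Iterable[FrameDetections],
    side: Iterable[FrameDetections],
) -> list[SynchronizedPair]:
    """Match the two camera streams on frame_index.

    The output covers the union of frame indices in increasing order; an
    index present in only one stream yields a pair with the other view set
    to None.  A duplicated frame_index within one stream is an error.
    """
    by_view: dict[str, dict[int, FrameDetections]] = {TOP: {}, SIDE: {}}
    for view, stream in ((TOP, top), (SIDE, side)):
        for frame in stream:
            if frame.camera != view:
                raise StreamError(
                    f"frame {frame.frame_index} tagged {frame.camera!r} "
                    f"in the {view} stream"
                )
            if frame.frame_index in by_view[view]:
                raise StreamError(
                    f"duplicate frame_index {frame.frame_index} in {view} stream"
                )
            by_view[view][frame.frame_index] = frame

    pairs: list[SynchronizedPair] = []
    for idx in sorted(set(by_view[TOP]) | set(by_view[SIDE])):
        t = by_view[TOP].get(idx)
        s = by_view[SIDE].get(idx)
        ts_candidates = [f.timestamp_s for f in (t, s) if f is not None]
        if len(ts_candidates) == 2 and abs(ts_candidates[0] - ts_candidates[1]) > 1e-9:
            raise StreamError(
                f"frame {idx}: top/side timestamps disagree "
                f"({ts_candidates[0]} vs {ts_candidates[1]})"
            )
        pairs.append(SynchronizedPair(idx, ts_candidates[0], top=t, side=s))
    return pairs


# ---------------------------------------------------------------------------
# filesystem / CSV interfaces

_FRAME_SUFFIX_RE = re.compile(r"(\d+)$")


def frame_index_from_name(path: str | Path) -> int:
    """Frame index = the numeric suffix of the filename stem (``img_0042.txt`` -> 42)."""
    stem = Path(path).stem
    m = _FRAME_SUFFIX_RE.search(stem)
    if m is None:
        raise YoloParseError(f"no numeric frame suffix in filename {path!r}")
    return int(m.group(1))


def read_yolo_dir(
    directory: str | Path,
    camera: str,
    dt_s: float = DEFAULT_DT_S,
    pattern: str = "*.txt",
) -> list[FrameDetections]:
    """Read one YOLO txt file per frame from ``directory``, sorted by frame index."""
    directory = Path(directory)
    frames = []
    for path in directory.glob(pattern):
        idx = frame_index_from_name(path)
        try:
            frames.append(parse_yolo_frame(path.read_text(), camera, idx, dt_s))
        except YoloParseError as exc:
            raise YoloParseError(f"{path}: {exc}") from None
    frames.sort(key=lambda f: f.frame_index)
    seen = [f.frame_index for f in frames]
    if len(set(seen)) != len(seen):
        raise StreamError(f"duplicate frame indices among files in {directory}")
    return frames


def write_yolo_dir(
    frames: Sequence[FrameDetections],
    directory: str | Path,
    prefix: str = "frame_",
    pad: int = 6,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        name = f"{prefix}{frame.frame_index:0{pad}d}.txt"
        (directory / name).write_text(format_yolo_frame(frame))


def stream_to_frame(frames: Sequence[FrameDetections]) -> pd.DataFrame:
    """Flatten a stream into the consolidated CSV table (one row per detection;
    a missed frame becomes one row with empty detection columns)."""
    rows = []
    for f in frames:
        if f.is_empty:
            rows.append((f.camera, f.frame_index, f.timestamp_s,
                         None, None, None, None, None, None))
        for d in f.detections:
            rows.append((f.camera, f.frame_index, f.timestamp_s,
                         d.class_id, d.cx, d.cy, d.w, d.h, d.confidence))
    return pd.DataFrame(rows, columns=STREAM_CSV_COLUMNS)


def write_stream_csv(frames: Sequence[FrameDetections], path: str | Path) -> None:
    stream_to_frame(frames).to_csv(path, index=False, float_format="%.6f")


def read_stream_csv(path: str | Path) -> list[FrameDetections]:
    df = pd.read_csv(path)
    missing = set(STREAM_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise StreamError(f"{path}: missing columns {sorted(missing)}")
    frames: list[FrameDetections] = []
    for (camera, idx), grp in df.groupby(["camera", "frame_index"], sort=True):
        ts = float(grp["timestamp_s"].iloc[0])
        dets = []
        for row in grp.itertuples(index=False):
            if pd.isna(row.class_id):
                continue
            dets.append(Detection(int(row.class_id), row.cx, row.cy, row.w, row.h,
                                  float(row.confidence)))
        frames.append(FrameDetections(str(camera), int(idx), ts, tuple(dets)))
    frames.sort(key=lambda f: (f.camera, f.frame_index))
    return frames


def split_stream_by_camera(
    frames: Sequence[FrameDetections],
) -> dict[str, list[FrameDetections]]:
    out: dict[str, list[FrameDetections]] = {TOP: [], SIDE: []}
    for f in frames:
        out[f.camera].append(f)
    return out
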