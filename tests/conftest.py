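import pytest

from fishtrack3d import default_geometry
from fishtrack3d.detection_io import SIDE, TOP, Detection, FrameDetections


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def tank(geometry):
    return geometry.tank


def make_frame(camera=TOP, frame_index=0, confs=(), dt_s=0.1, cx=0.5, cy=0.5):
    """A frame with one centered 0.1x0.1 detection per confidence value."""
    dets = tuple(
        Detection(0, cx, cy, 0.1, 0.1, confidence=c) for c in confs
    )
    return FrameDetections(camera, frame_index, frame_index * dt_s, dets)
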