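import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from frontgait.heightsignal import HeightSignal
from frontgait.videotrack import DetectionSeries, FrameDetection

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_signal(values, stage="normalized", fps=25.0, recording_id="test"):
    return HeightSignal(recording_id=recording_id, fps=fps, values=np.asarray(values, float), stage=stage)


def make_series(heights, faces=None, widths=None, fps=25.0, recording_id="test"):
    """Detection series from plain lists; None marks a missing detection."""
    n = len(heights)
    faces = faces if faces is not None else [None] * n
    widths = widths if widths is not None else [None] * n
    frames = [
        FrameDetection(
            frame_index=i,
            person_height_px=heights[i],
            person_width_px=widths[i],
            face_height_px=faces[i],
        )
        for i in range(n)
    ]
    return DetectionSeries(recording_id=recording_id, fps=fps, frames=frames)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
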