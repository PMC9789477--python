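"""Height-signal preprocessing.

Turns a per-frame detection series into the amplitude signal the gait
features are computed from.  The pipeline stages are, in order:

``raw`` -> ``face_scaled`` -> ``normalized`` -> ``smoothed`` -> ``quantized``

* face scaling divides silhouette height Sh by face height fh per frame,
  removing inter-subject stature differences (face height is roughly
  proportional to body height);
* min-max normalization maps the scaled signal onto [0, 1], removing the
  effect of camera distance;
* a centered moving average suppresses frame-to-frame detection jitter;
* quantization replaces consecutive fixed-size partitions of frames with
  their mean, producing the piecewise-constant plateau signal on which gait
  events are read off;
* the walk is split into forward/backward halves at the first global
  maximum — the point where the subject is closest to the camera.

Each operation checks the stage of its input and raises
:class:`~frontgait.exceptions.StageError` on misuse, so the stages cannot be
applied out of order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .exceptions import (
    DegenerateSignalError,
    InputError,
    MissingScaleError,
    StageError,
    UnusableTrackError,
)
from .videotrack import DetectionSeries, FrameDetection

STAGES = ("raw", "face_scaled", "normalized", "smoothed", "quantized")


@dataclass
class HeightSignal:
    """A 1-D amplitude series at a known processing stage.

    ``values[i]`` corresponds to frame ``i`` of the (sub)recording; time in
    seconds is ``i / fps``.
    """

    recording_id: str
    fps: float
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("values must be a 1-D series")
        if not self.fps > 0:
            raise InputError("fps must be positive")
        if self.stage not in STAGES:
            raise InputError(f"unknown stage {self.stage!r}")
        if np.isnan(self.values).any():
            raise InputError("HeightSignal must not contain NaN (fill gaps first)")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, stage: str) -> "HeightSignal":
        return HeightSignal(self.recording_id, self.fps, np.asarray(values, float), stage)


def require_stage(signal: HeightSignal, allowed: tuple[str, ...]) -> None:
    if signal.stage not in allowed:
        raise StageError(
            f"operation expects stage in {allowed}, got {signal.stage!r} "
            f"(recording {signal.recording_id!r})"
        )


@dataclass
class WalkSegments:
    """Forward/backward halves of a walk, split at the height maximum.

    ``forward`` covers frames [0, split_index] and ``backward`` covers
    [split_index, end]; the split frame belongs to both.
    """

    forward: HeightSignal
    backward: HeightSignal
    split_index: int

    def full_values(self) -> np.ndarray:
        """The complete walk, re-assembled without duplicating the split frame."""
        return np.concatenate([self.forward.values, self.backward.values[1:]])


def fill_gaps(series: DetectionSeries) -> DetectionSeries:
    """Fill missing person heights: linear interpolation of interior gaps,
    nearest-value hold at the edges.  Face heights are left untouched (the
    scaling policy handles those)."""
    heights = series.person_heights()
    valid = ~np.isnan(heights)
    if valid.sum() < 2:
        raise UnusableTrackError(
            f"need at least 2 person detections, got {int(valid.sum())} "
            f"(recording {series.recording_id!r})"
        )
    idx = np.arange(len(heights))
    filled = np.interp(idx, idx[valid], heights[valid])
    frames = [
        dc_replace(f, person_height_px=float(h)) if f.person_height_px is None else f
        for f, h in zip(series.frames, filled)
    ]
    return DetectionSeries(series.recording_id, series.fps, frames)


def scale_by_face_height(
    series: DetectionSeries,
    fh_policy: str = "median",
    constant_fh: float | None = None,
) -> HeightSignal:
    """Divide each person height by a face height -> stage ``face_scaled``.

    Policies:
      * ``median`` (default): one constant per recording — the median of all
        detected face heights.  Because the detected face scales with camera
        distance exactly like the silhouette does, dividing by the
        *concurrent* face height would cancel the approach signal itself;
        a per-recording constant removes stature while preserving the walk.
      * ``frame_or_median``: use the frame's own face detection when present,
        falling back to the median; only sensible with a face detector that
        fires sporadically and whose output does not track distance.

    ``constant_fh`` overrides both policies.  Raises
    :class:`MissingScaleError` if no face height is available at all.
    """
    heights = series.person_heights()
    if np.isnan(heights).any():
        raise InputError("person heights contain gaps; run fill_gaps first")
    faces = series.face_heights()
    detected = faces[~np.isnan(faces)]

    if constant_fh is not None:
        if not constant_fh > 0:
            raise InputError("constant_fh must be positive")
        fh = np.full_like(heights, float(constant_fh))
    else:
        if detected.size == 0:
            raise MissingScaleError(
                f"no face height detected and none supplied (recording {series.recording_id!r})"
            )
        if (detected <= 0).any():
            raise InputError("face heights must be positive")
        median_fh = float(np.median(detected))
        if fh_policy == "frame_or_median":
            fh = np.where(np.isnan(faces), median_fh, faces)
        elif fh_policy == "median":
            fh = np.full_like(heights, median_fh)
        else:
            raise InputError(f"unknown fh_policy {fh_policy!r}")
    if (fh <= 0).any():
        raise InputError("face heights must be positive")
    return HeightSignal(series.recording_id, series.fps, heights / fh, stage="face_scaled")


def minmax_normalize(signal: HeightSignal) -> HeightSignal:
    """Map the scaled signal onto [0, 1]: (x - min) / (max - min)."""
    require_stage(signal, ("face_scaled",))
    x = signal.values
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError(
            f"constant signal cannot be normalized (recording {signal.recording_id!r})"
        )
    return signal.with_values((x - lo) / (hi - lo), stage="normalized")


def moving_average(signal: HeightSignal, window: int = 5) -> HeightSignal:
    """Centered moving average with shrinking windows at the edges.

    The output has the same length as the input; the default 5-frame window
    is 0.2 s at 25 fps, matching the quantization partition.
    """
    require_stage(signal, ("normalized",))
    if window < 1 or window % 2 == 0:
        raise InputError("window must be a positive odd integer")
    n = len(signal.values)
    if window > n:
        raise InputError(f"window {window} exceeds signal length {n}")
    kernel = np.ones(window)
    sums = np.convolve(signal.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return signal.with_values(sums / counts, stage="smoothed")


def lloyd_quantize(signal: HeightSignal, partition_size: int = 5) -> HeightSignal:
    """Replace consecutive ``partition_size``-frame partitions by their mean.

    Maps every partition to the (uniformly weighted) centroid of its points,
    producing the piecewise-constant plateau signal; a shorter tail partition
    is allowed.  Idempotent for a fixed partition size.
    """
    require_stage(signal, ("smoothed", "quantized"))
    if partition_size < 1:
        raise InputError("partition_size must be >= 1")
    x = signal.values
    if len(x) < partition_size:
        raise InputError(f"signal length {len(x)} shorter than partition {partition_size}")
    out = np.empty_like(x)
    for start in range(0, len(x), partition_size):
        block = slice(start, start + partition_size)
        out[block] = x[block].mean()
    return signal.with_values(out, stage="quantized")


def split_walks(signal: HeightSignal) -> WalkSegments:
    """Split at the first frame attaining the global maximum height.

    The maximum marks the position closest to the camera, i.e. the turn
    between the forward and backward walks.  A maximum at the first or last
    frame produces a one-sided-walk warning (not an error).
    """
    require_stage(signal, ("normalized", "smoothed", "quantized"))
    x = signal.values
    split = int(np.argmax(x))  # argmax returns the first occurrence
    if split == 0 or split == len(x) - 1:
        warnings.warn(
            f"height maximum at the {'first' if split == 0 else 'last'} frame: "
            f"one-sided walk (recording {signal.recording_id!r})",
            stacklevel=2,
        )
    forward = signal.with_values(x[: split + 1], stage=signal.stage)
    backward = signal.with_values(x[split:], stage=signal.stage)
    return WalkSegments(forward=forward, backward=backward, split_index=split)
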