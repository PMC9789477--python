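"""Gait-event detection and the five gait features.

From the quantized forward-walk signal this module reads off gait events
(points of amplitude increase: the silhouette grows each time the legs pass
each other and a new step lands), alternates the inter-event intervals as
stance/swing phases, and computes:

=============  ===============================================================
``S_avg``      mean stride time in seconds (stance + swing over consecutive
               event pairs); low values indicate short steps
``alpha``      detrended-fluctuation-analysis (DFA) scaling exponent of the
               normalized walk; captures irregular, shuffling progression
``E``          amplitude entropy  -sum(x * log2 x)  of the normalized walk
``A_delta_C``  mean difference between consecutive short-window spectral
               centroids (Hz); weak/unstable centroids accompany festination
``T``          valley-to-peak time in seconds (how long the subject takes to
               get from farthest to closest); a direct walking-speed proxy
=============  ===============================================================

together forming the :class:`FeatureVector` used for severity classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import heightsignal as hs
from .exceptions import (
    DegenerateSignalError,
    GaitPipelineError,
    InputError,
    InsufficientEventsError,
)
from .heightsignal import HeightSignal, WalkSegments
from .videotrack import DetectionSeries

FEATURE_NAMES = ("S_avg", "alpha", "E", "A_delta_C", "T")


@dataclass
class GaitEventSeries:
    """Ordered gait-event timestamps in seconds, measured from segment start."""

    timestamps_s: np.ndarray
    source_segment: str = "forward"

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise InputError("event timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps_s)


@dataclass
class StridePhases:
    """Alternating stance/swing intervals paired into N strides."""

    stance_times_s: np.ndarray
    swing_times_s: np.ndarray
    stride_times_s: np.ndarray

    @property
    def n_strides(self) -> int:
        return len(self.stride_times_s)


@dataclass
class FeatureVector:
    """The five gait features of one recording; NaN + flag marks a failure."""

    recording_id: str
    S_avg: float = np.nan
    alpha: float = np.nan
    E: float = np.nan
    A_delta_C: float = np.nan
    T: float = np.nan
    label: Optional[int] = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_complete(self) -> bool:
        return not self.flags and np.isfinite(
            [self.S_avg, self.alpha, self.E, self.A_delta_C, self.T]
        ).all()

    def as_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "S_avg": self.S_avg,
            "alpha": self.alpha,
            "E": self.E,
            "A_delta_C": self.A_delta_C,
            "T": self.T,
            "label": self.label,
        }


def _values(signal) -> np.ndarray:
    if isinstance(signal, HeightSignal):
        return signal.values
    return np.asarray(signal, dtype=float)


# ---------------------------------------------------------------------------
# events and stride timing
# ---------------------------------------------------------------------------

def detect_events(
    quantized_forward: HeightSignal,
    partition_size: int = 5,
    min_rise: float = 0.01,
) -> GaitEventSeries:
    """Detect gait events on the quantized forward-walk signal.

    The quantized signal is a sequence of plateaus, one per
    ``partition_size``-frame partition (the same size used for
    quantization).  An event is a plateau whose increment over the preceding
    plateau (i) exceeds ``min_rise`` and (ii) is a local maximum of the
    increment sequence — the locally steepest point of amplitude increase.
    The local-maximum condition assigns exactly one event to each physical
    rise even when the rise ramp is smeared across neighbouring partitions by
    smoothing and partition averaging, and ``min_rise`` (in normalized
    amplitude units) suppresses noise-level wobble between plateaus of equal
    true height.

    The event timestamp is the starting frame of the plateau divided by fps.
    Raises :class:`InsufficientEventsError` with fewer than two events.
    """
    hs.require_stage(quantized_forward, ("quantized",))
    if partition_size < 1:
        raise InputError("partition_size must be >= 1")
    x = quantized_forward.values
    if len(x) < 2 * partition_size:
        raise InputError("signal too short for event detection")
    starts = np.arange(0, len(x), partition_size)
    plateau_values = x[starts]
    d = np.diff(plateau_values)  # d[k] = increment of plateau k+1 over plateau k
    padded = np.concatenate([[0.0], d, [0.0]])
    timestamps = []
    for k in range(len(d)):
        if d[k] > min_rise and d[k] > padded[k] and d[k] >= padded[k + 2]:
            timestamps.append(starts[k + 1] / quantized_forward.fps)
    if len(timestamps) < 2:
        raise InsufficientEventsError(
            f"only {len(timestamps)} gait event(s) detected "
            f"(recording {quantized_forward.recording_id!r})"
        )
    return GaitEventSeries(np.asarray(timestamps), source_segment="forward")


def stride_phases(events: GaitEventSeries) -> StridePhases:
    """Alternate inter-event intervals as stance/swing and pair them into strides.

    With events Ts(1..n): stance = Ts(i+1)-Ts(i), swing = Ts(i+2)-Ts(i+1) for
    odd i, stride = stance + swing over non-overlapping pairs; a trailing
    unpaired interval is dropped.
    """
    ts = events.timestamps_s
    if len(ts) < 3:
        raise InsufficientEventsError(f"need >= 3 events for a stride, got {len(ts)}")
    d = np.diff(ts)
    n_strides = len(d) // 2
    stance = d[0::2][:n_strides]
    swing = d[1::2][:n_strides]
    return StridePhases(stance, swing, stance + swing)


def avg_stride_time(phases: StridePhases) -> float:
    """Mean stride time S_avg in seconds."""
    if phases.n_strides < 1:
        raise InsufficientEventsError("no strides available")
    return float(np.mean(phases.stride_times_s))


# ---------------------------------------------------------------------------
# signal-level features
# ---------------------------------------------------------------------------

def dfa_alpha(signal, box_size_l: int = 5) -> float:
    """DFA scaling exponent alpha.

    The signal is integrated (cumulative sum of deviations from its mean) and
    divided into non-overlapping boxes of size l, 2l, 3l, ... up to length/4.
    Each box is detrended by its least-squares line; F(l) is the RMS residual
    pooled over all boxes of that size.  alpha is the slope of the ordinary
    least-squares fit of log F(l) versus log l.  alpha ~ 0.5 for white noise,
    ~ 1 for 1/f (self-similar) noise, ~ 1.5 for Brownian motion.
    """
    x = _values(signal)
    n = len(x)
    if box_size_l < 2:
        raise InputError("box_size_l must be >= 2")
    sizes = box_size_l * np.arange(1, (n // 4) // box_size_l + 1)
    if len(sizes) < 4:
        raise InputError(
            f"signal of length {n} too short for DFA with box size {box_size_l} "
            "(need at least 4 box sizes)"
        )
    y = np.cumsum(x - x.mean())
    fluctuations = np.empty(len(sizes))
    for i, s in enumerate(sizes):
        n_boxes = n // s
        boxes = y[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s, dtype=float)
        t_mean = t.mean()
        t_var = ((t - t_mean) ** 2).sum()
        box_means = boxes.mean(axis=1, keepdims=True)
        slopes = ((boxes - box_means) * (t - t_mean)).sum(axis=1, keepdims=True) / t_var
        residuals = boxes - box_means - slopes * (t - t_mean)
        fluctuations[i] = np.sqrt(np.mean(residuals**2))
    if np.any(fluctuations == 0):
        raise DegenerateSignalError("zero fluctuation at some scale (constant signal?)")
    slope, _ = np.polyfit(np.log(sizes), np.log(fluctuations), 1)
    return float(slope)


def entropy(signal) -> float:
    """Amplitude entropy E = -sum(x * log2 x) over the normalized samples.

    Applied to amplitudes in [0, 1] (not a probability distribution); the
    term for x = 0 is taken as 0 by the limit convention.  Order-free.
    """
    x = _values(signal)
    if isinstance(signal, HeightSignal):
        hs.require_stage(signal, ("normalized", "smoothed", "quantized"))
    if np.any(x < 0) or np.any(x > 1):
        raise InputError("entropy expects values in [0, 1] (normalize first)")
    terms = np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)
    return float(-terms.sum())


def spectral_centroids(signal, box_n: int = 5, fps: Optional[float] = None) -> np.ndarray:
    """Magnitude-weighted mean frequency (Hz) of consecutive ``box_n``-sample boxes.

    For each non-overlapping box the discrete-Fourier magnitude spectrum over
    the non-negative frequencies f_i = i * fps / box_n is computed and the
    centroid is C = sum(f_i x_i) / sum(x_i); an all-zero box yields C = 0.
    A shorter tail box is dropped.
    """
    x = _values(signal)
    if box_n < 2:
        raise InputError("box_n must be >= 2")
    if fps is None:
        if isinstance(signal, HeightSignal):
            fps = signal.fps
        else:
            raise InputError("fps required when signal is a plain array")
    if len(x) < box_n:
        raise InputError(f"signal length {len(x)} shorter than box size {box_n}")
    n_boxes = len(x) // box_n
    boxes = x[: n_boxes * box_n].reshape(n_boxes, box_n)
    mags = np.abs(np.fft.rfft(boxes, axis=1))
    freqs = np.fft.rfftfreq(box_n, d=1.0 / fps)
    denom = mags.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = np.where(denom > 0, (mags * freqs).sum(axis=1) / denom, 0.0)
    return centroids


def centroid_variability(centroids, absolute: bool = False) -> float:
    """Mean difference between consecutive centroids, A_delta_C.

    As printed the statistic is the *signed* mean sum(C_i - C_{i-1}) / N with
    N the number of centroids; ``absolute=True`` switches to the
    absolute-difference variant.
    """
    c = np.asarray(centroids, dtype=float)
    if len(c) < 2:
        raise InputError("need at least 2 centroids")
    diffs = np.diff(c)
    if absolute:
        diffs = np.abs(diffs)
    return float(diffs.sum() / len(c))


def valley_peak_time(signal, fps: Optional[float] = None) -> float:
    """Time in seconds between the signal's valley and peak (first occurrences)."""
    x = _values(signal)
    if fps is None:
        if isinstance(signal, HeightSignal):
            fps = signal.fps
        else:
            raise InputError("fps required when signal is a plain array")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant signal has no valley/peak")
    return float(abs(int(np.argmax(x)) - int(np.argmin(x))) / fps)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_features(
    segments: WalkSegments,
    *,
    smoothing_window: int = 5,
    partition_size: int = 5,
    box_size_l: int = 5,
    box_n: int = 5,
    feature_segment: str = "full",
    abs_centroid_diff: bool = False,
    min_rise: float = 0.01,
    recording_id: Optional[str] = None,
    label: Optional[int] = None,
) -> FeatureVector:
    """Compute the five-feature vector for one recording.

    Gait events and S_avg are computed on the forward segment after smoothing
    and quantization; alpha, E, A_delta_C and T are computed on the normalized
    signal — the full walk by default, or the forward segment when
    ``feature_segment="forward"``.  A feature whose computation fails on a
    degenerate recording leaves NaN and a flag naming the failure; such
    incomplete vectors are excluded from model training by the callers.
    """
    if feature_segment not in ("full", "forward"):
        raise InputError(f"feature_segment must be 'full' or 'forward', got {feature_segment!r}")
    forward = segments.forward
    rec = recording_id if recording_id is not None else forward.recording_id
    fv = FeatureVector(recording_id=rec, label=label)
    flags = []

    try:
        smoothed = hs.moving_average(forward, window=smoothing_window)
        quantized = hs.lloyd_quantize(smoothed, partition_size=partition_size)
        events = detect_events(quantized, partition_size=partition_size, min_rise=min_rise)
        fv.S_avg = avg_stride_time(stride_phases(events))
    except GaitPipelineError as exc:
        flags.append(f"S_avg:{type(exc).__name__}")

    if feature_segment == "full":
        chosen = HeightSignal(rec, forward.fps, segments.full_values(), stage=forward.stage)
    else:
        chosen = forward

    for name, fn in (
        ("alpha", lambda: dfa_alpha(chosen, box_size_l=box_size_l)),
        ("E", lambda: entropy(chosen)),
        (
            "A_delta_C",
            lambda: centroid_variability(
                spectral_centroids(chosen, box_n=box_n), absolute=abs_centroid_diff
            ),
        ),
        ("T", lambda: valley_peak_time(chosen)),
    ):
        try:
            setattr(fv, name, fn())
        except GaitPipelineError as exc:
            flags.append(f"{name}:{type(exc).__name__}")

    fv.flags = tuple(flags)
    return fv


class GaitFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer: detection series -> gait-feature table.

    ``transform`` accepts an iterable of :class:`DetectionSeries` and returns
    a :class:`pandas.DataFrame` with columns ``recording_id``, the five
    features, ``label`` (NaN; labels are joined downstream) and ``flags``.
    Stateless — ``fit`` only validates parameters — so it composes with
    sklearn pipelines and cross-validation without leakage concerns.
    """

    def __init__(
        self,
        smoothing_window: int = 5,
        partition_size: int = 5,
        box_size_l: int = 5,
        box_n: int = 5,
        feature_segment: str = "full",
        abs_centroid_diff: bool = False,
        min_rise: float = 0.01,
        fh_policy: str = "median",
    ) -> None:
        self.smoothing_window = smoothing_window
        self.partition_size = partition_size
        self.box_size_l = box_size_l
        self.box_n = box_n
        self.feature_segment = feature_segment
        self.abs_centroid_diff = abs_centroid_diff
        self.min_rise = min_rise
        self.fh_policy = fh_policy

    def fit(self, X: Iterable[DetectionSeries], y=None) -> "GaitFeatureExtractor":
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise InputError("smoothing_window must be a positive odd integer")
        if self.partition_size < 1:
            raise InputError("partition_size must be >= 1")
        return self

    def extract_one(self, series: DetectionSeries, label: Optional[int] = None) -> FeatureVector:
        """Full preprocessing + feature chain for one recording."""
        try:
            filled = hs.fill_gaps(series)
            scaled = hs.scale_by_face_height(filled, fh_policy=self.fh_policy)
            normalized = hs.minmax_normalize(scaled)
            with np.errstate(all="ignore"):
                segments = hs.split_walks(normalized)
        except GaitPipelineError as exc:
            return FeatureVector(
                recording_id=series.recording_id,
                label=label,
                flags=(f"preprocess:{type(exc).__name__}",),
            )
        return extract_features(
            segments,
            smoothing_window=self.smoothing_window,
            partition_size=self.partition_size,
            box_size_l=self.box_size_l,
            box_n=self.box_n,
            feature_segment=self.feature_segment,
            abs_centroid_diff=self.abs_centroid_diff,
            min_rise=self.min_rise,
            recording_id=series.recording_id,
            label=label,
        )

    def transform(self, X: Iterable[DetectionSeries]) -> pd.DataFrame:
        rows = []
        for series in X:
            fv = self.extract_one(series)
            row = fv.as_dict()
            row["flags"] = ";".join(fv.flags)
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["recording_id", *FEATURE_NAMES, "label", "flags"],
        )


def write_feature_csv(table: pd.DataFrame, path) -> None:
    cols = ["recording_id", *FEATURE_NAMES, "label"]
    table.loc[:, cols].to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"recording_id", *FEATURE_NAMES} - set(table.columns)
    if missing:
        raise InputError(f"feature CSV missing columns: {sorted(missing)}")
    return table
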