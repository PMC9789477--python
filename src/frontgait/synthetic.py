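"""Synthetic front-view gait walks with ground truth.

No public recordings of clinical UPDRS-gait walks exist, so every pipeline
test runs on simulated walks whose generating parameters are known.  The
simulator reproduces the morphology the pipeline assumes:

* the silhouette height rises in a staircase toward a maximum while the
  subject approaches the camera: per stride, two plateau-and-rise steps
  (terminal-stance and terminal-swing), since the apparent height grows each
  time the legs spread;
* a dwell at the maximum while the subject turns;
* a mirrored descending staircase while walking away;
* class-dependent cadence, amplitude, irregularity, festination bursts
  (level 2: a stride replaced by 2-3 quick short rises), and additive
  detection noise;
* face height proportional to silhouette height with small per-frame noise.

Class default profiles encode the qualitative clinical contrasts: healthy
walks are fastest with large regular steps, level 1 is slower with smaller,
more irregular steps, and level 2 is slowest with the smallest steps and
festination.  All outputs are deterministic given (profile, fps, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import InputError
from .videotrack import DetectionSeries, FrameDetection

#: per-class parameter ranges (uniform draws) for profile sampling
CLASS_PROFILE_RANGES = {
    0: dict(
        cadence_strides_per_s=(0.95, 1.15),
        step_amplitude=(1.0, 1.3),
        amplitude_jitter=(0.02, 0.06),
        cadence_jitter=(0.02, 0.05),
        festination_rate=(0.0, 0.0),
        turn_dwell_s=(0.4, 0.8),
        forward_duration_s=(5.5, 7.5),
        noise_sd=(0.006, 0.010),
    ),
    1: dict(
        cadence_strides_per_s=(0.70, 0.88),
        step_amplitude=(0.55, 0.80),
        amplitude_jitter=(0.10, 0.18),
        cadence_jitter=(0.08, 0.14),
        festination_rate=(0.0, 0.0),
        turn_dwell_s=(0.8, 1.4),
        forward_duration_s=(8.0, 11.0),
        noise_sd=(0.008, 0.014),
    ),
    2: dict(
        cadence_strides_per_s=(0.50, 0.68),
        step_amplitude=(0.30, 0.50),
        amplitude_jitter=(0.15, 0.25),
        cadence_jitter=(0.12, 0.20),
        festination_rate=(0.25, 0.40),
        turn_dwell_s=(1.2, 2.2),
        forward_duration_s=(11.0, 15.0),
        noise_sd=(0.010, 0.018),
    ),
}


@dataclass(frozen=True)
class GaitProfile:
    """Generating parameters of one synthetic walk.

    ``noise_sd`` is the detection-noise standard deviation as a fraction of
    the total height span (a ~1-2 px bounding-box jitter on a ~120 px span
    is ~0.01); ``step_amplitude`` is the per-stride height increment in
    pre-normalization units (only ratios matter after normalization).
    """

    label: int
    cadence_strides_per_s: float
    step_amplitude: float
    amplitude_jitter: float = 0.05
    cadence_jitter: float = 0.05
    festination_rate: float = 0.0
    turn_dwell_s: float = 0.6
    forward_duration_s: float = 7.0
    noise_sd: float = 0.01
    subject_height_px: float = 200.0
    face_ratio: float = 0.16

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise InputError(f"profile field {f.name} must be finite")
        if self.label not in (0, 1, 2):
            raise InputError("label must be 0, 1 or 2")
        if not self.cadence_strides_per_s > 0:
            raise InputError("cadence must be positive")
        if not self.step_amplitude > 0:
            raise InputError("step_amplitude must be positive")
        if not self.forward_duration_s > 0:
            raise InputError("forward_duration_s must be positive")
        if not 0 < self.face_ratio < 0.5:
            raise InputError("face_ratio must be in (0, 0.5)")
        for name in ("amplitude_jitter", "cadence_jitter", "festination_rate",
                     "turn_dwell_s", "noise_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


def profile_for_label(label: int, rng: np.random.Generator) -> GaitProfile:
    """Draw a profile uniformly from the class-default ranges."""
    if label not in CLASS_PROFILE_RANGES:
        raise InputError(f"no profile ranges for label {label}")
    ranges = CLASS_PROFILE_RANGES[label]
    kwargs = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    kwargs["subject_height_px"] = float(rng.uniform(170.0, 240.0))
    kwargs["face_ratio"] = float(rng.uniform(0.13, 0.18))
    return GaitProfile(label=label, **kwargs)


@dataclass
class SyntheticWalk:
    """One simulated walk plus the ground truth the pipeline should recover."""

    series: DetectionSeries
    truth_events_s: np.ndarray  # forward-walk step timestamps (rise completions)
    truth_split_index: int  # first frame attaining the maximum height
    truth_stride_count: int  # full strides in the forward walk
    profile: GaitProfile
    fps: float
    seed: int


def _forward_steps(profile: GaitProfile, rng: np.random.Generator) -> tuple[list, int]:
    """Draw the forward-walk step list [(duration_s, rise), ...].

    Each stride is two steps; a festination burst replaces a stride with 2-3
    quicker, shorter rises compressed into ~60% of the stride period.
    """
    step_period = 1.0 / (2.0 * profile.cadence_strides_per_s)
    steps: list[tuple[float, float]] = []
    t = 0.0
    n_strides = 0
    while t < profile.forward_duration_s:
        if profile.festination_rate > 0 and rng.random() < profile.festination_rate:
            k = int(rng.integers(2, 4))
            for _ in range(k):
                dur = (2.0 * step_period * 0.6 / k) * max(0.3, 1.0 + 0.5 * profile.cadence_jitter * rng.standard_normal())
                rise = (2.0 * profile.step_amplitude / (k + 1.0)) * max(
                    0.1, 1.0 + profile.amplitude_jitter * rng.standard_normal()
                )
                steps.append((dur, rise))
                t += dur
            n_strides += 1
            continue
        for _ in range(2):  # stance step, swing step
            dur = step_period * max(0.3, 1.0 + profile.cadence_jitter * rng.standard_normal())
            rise = profile.step_amplitude * max(
                0.1, 1.0 + profile.amplitude_jitter * rng.standard_normal()
            )
            steps.append((dur, rise))
            t += dur
        n_strides += 1
    return steps, n_strides


def simulate_height_signal(
    profile: GaitProfile, fps: float = 25.0, seed: int = 0
) -> SyntheticWalk:
    """Simulate the detection series of one walk.

    The forward staircase holds a plateau for most of each step and ramps up
    over ~0.1 s at the step's end; stride boundaries follow the profile
    cadence with multiplicative jitter.  The full walk is forward staircase +
    turn dwell + time-mirrored descent, scaled into pixel heights between 35%
    (farthest) and 100% (closest) of the subject's near-camera height, with
    additive Gaussian detection noise.
    """
    if not fps > 0:
        raise InputError("fps must be positive")
    rng = np.random.default_rng(seed)
    steps, n_strides = _forward_steps(profile, rng)
    if len(steps) < 2:
        raise InputError("profile produces fewer than 2 steps; increase duration or cadence")

    # knots of the piecewise-linear staircase u(t)
    t_knots, u_knots = [0.0], [0.0]
    truth_events = []
    t, level = 0.0, 0.0
    for dur, rise in steps:
        ramp = min(0.10, 0.4 * dur)
        t_knots.append(t + dur - ramp)
        u_knots.append(level)
        level += rise
        t += dur
        t_knots.append(t)
        u_knots.append(level)
        truth_events.append(t)
    total_fwd = t

    n_fwd = int(round(total_fwd * fps))
    frame_t = np.arange(n_fwd) / fps
    u_fwd = np.interp(frame_t, t_knots, u_knots)
    n_dwell = int(round(profile.turn_dwell_s * fps))
    u = np.concatenate([u_fwd, np.full(n_dwell, level), u_fwd[::-1]])

    peak = u.max()
    s = u / peak
    truth_split_index = int(np.argmax(s))

    near = profile.subject_height_px
    far = 0.35 * near
    span = near - far
    sh = far + s * span
    sh = sh + rng.normal(0.0, profile.noise_sd * span, size=len(sh))
    sh = np.clip(sh, 5.0, None)
    fh = profile.face_ratio * sh * (1.0 + 0.01 * rng.standard_normal(len(sh)))
    fh = np.clip(fh, 1.0, 0.45 * sh)
    sw = 0.35 * sh

    frames = [
        FrameDetection(i, float(sh[i]), float(sw[i]), float(fh[i])) for i in range(len(sh))
    ]
    series = DetectionSeries(
        recording_id=f"sim-{profile.label}-{seed}", fps=fps, frames=frames
    )
    return SyntheticWalk(
        series=series,
        truth_events_s=np.asarray(truth_events),
        truth_split_index=truth_split_index,
        truth_stride_count=n_strides,
        profile=profile,
        fps=fps,
        seed=seed,
    )


def simulate_dataset(
    n_per_class: int, fps: float = 25.0, seed: int = 0
) -> tuple[list[SyntheticWalk], pd.DataFrame]:
    """Generate a balanced labelled dataset of 3 * n_per_class walks.

    Per-walk seeds are derived from the master seed (and logged in the label
    table) so that any single walk can be regenerated in isolation.
    """
    if n_per_class < 1:
        raise InputError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    walks, rows = [], []
    for label in (0, 1, 2):
        for i in range(n_per_class):
            profile_seed = int(master.integers(0, 2**31 - 1))
            signal_seed = int(master.integers(0, 2**31 - 1))
            profile = profile_for_label(label, np.random.default_rng(profile_seed))
            walk = simulate_height_signal(profile, fps=fps, seed=signal_seed)
            recording_id = f"sim-{label}-{i:03d}"
            walk.series.recording_id = recording_id
            walks.append(walk)
            rows.append({"recording_id": recording_id, "label": label, "seed": signal_seed})
    return walks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# silhouette rendering
# ---------------------------------------------------------------------------

_BG, _FG = 230, 25  # light background, dark silhouette


def _render_frame(
    height_px: int,
    face_px: int,
    resolution: tuple[int, int] = (352, 288),
    bottom_margin: int = 6,
) -> np.ndarray:
    """Draw one frame: a blocky upright figure (head/torso/legs) centered
    horizontally, feet on a fixed ground line."""
    width, height = resolution
    frame = np.full((height, width), _BG, dtype=np.uint8)
    if height_px < 8:
        raise InputError("sprite too small to render")
    if height_px > height - bottom_margin - 2:
        raise InputError(f"sprite height {height_px} does not fit frame height {height}")
    h = int(height_px)
    hh = max(2, int(face_px))
    top = height - bottom_margin - h
    cx = width // 2
    head_w = max(2, int(0.18 * h))
    torso_w = max(head_w + 4, int(0.42 * h))
    torso_h = int(0.42 * h)
    leg_w = max(2, int(0.12 * h))
    leg_gap = max(2, int(0.10 * h))
    # head
    frame[top : top + hh, cx - head_w // 2 : cx + head_w // 2 + 1] = _FG
    # torso
    frame[top + hh : top + hh + torso_h, cx - torso_w // 2 : cx + torso_w // 2 + 1] = _FG
    # legs
    legs_top = top + hh + torso_h
    legs_bottom = top + h
    frame[legs_top:legs_bottom, cx - leg_gap // 2 - leg_w : cx - leg_gap // 2] = _FG
    frame[legs_top:legs_bottom, cx + leg_gap // 2 : cx + leg_gap // 2 + leg_w] = _FG
    return frame


def render_silhouette_video(
    walk: SyntheticWalk,
    path,
    resolution: tuple[int, int] = (352, 288),
) -> None:
    """Render a walk as a deterministic silhouette video.

    Per frame a filled dark figure of the walk's scripted pixel height (head
    block = face height) stands on a light background.  The container format
    follows the file extension; multi-frame TIFF is lossless and always
    available, MP4/AVI additionally require an ffmpeg-capable imageio plugin.
    """
    stack = np.stack(
        [
            _render_frame(
                int(round(f.person_height_px)),
                int(round(f.face_height_px)),
                resolution=resolution,
            )
            for f in walk.series.frames
        ]
    )
    iio.imwrite(path, stack)
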