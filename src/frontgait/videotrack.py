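"""Person and face detection on front-view walking videos.

A walking subject filmed from the front grows in apparent (pixel) height as
they approach the camera and shrinks as they retreat.  This module turns a
video into a per-frame :class:`DetectionSeries` — silhouette bounding-box
height/width plus face height — which is the raw input of the height-signal
pipeline.

Detectors are injected behind a minimal interface (``detect(image) -> list of
boxes``) so that any person/face detector can be plugged in.  The default
:class:`SilhouetteDetector` segments a dark silhouette on a light background
(Otsu threshold + connected components); it is deterministic and is the
backend used for synthetic rendered walks.  Detection itself is deliberately
not the interesting part of the pipeline: single subject, static camera.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Protocol, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .exceptions import EmptyTrackError, InputError

DEFAULT_FPS = 25.0


class Box(NamedTuple):
    """Axis-aligned bounding box in pixel coordinates (x = column, y = row)."""

    x: float
    y: float
    width: float
    height: float


@dataclass(frozen=True)
class FrameDetection:
    """Detections for one video frame; ``None`` marks a failed detection."""

    frame_index: int
    person_height_px: Optional[float] = None
    person_width_px: Optional[float] = None
    face_height_px: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InputError("frame_index must be >= 0")
        if self.person_height_px is not None and not self.person_height_px > 0:
            raise InputError("person_height_px must be positive when present")
        if self.face_height_px is not None and not self.face_height_px > 0:
            raise InputError("face_height_px must be positive when present")
        if (
            self.person_height_px is not None
            and self.face_height_px is not None
            and self.face_height_px >= self.person_height_px
        ):
            raise InputError("face_height_px must be smaller than person_height_px")


@dataclass
class DetectionSeries:
    """Ordered per-frame detections of one recording.

    Invariants: frames sorted by unique frame index, positive fps, and at
    least one frame with a detected person.
    """

    recording_id: str
    fps: float
    frames: Sequence[FrameDetection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise InputError("fps must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InputError("frames must be sorted by strictly increasing frame_index")
        if not any(f.person_height_px is not None for f in self.frames):
            raise InputError("series must contain at least one person detection")

    def __len__(self) -> int:
        return len(self.frames)

    def person_heights(self) -> np.ndarray:
        """Per-frame person heights with NaN for missing detections."""
        return np.array(
            [np.nan if f.person_height_px is None else f.person_height_px for f in self.frames],
            dtype=float,
        )

    def face_heights(self) -> np.ndarray:
        return np.array(
            [np.nan if f.face_height_px is None else f.face_height_px for f in self.frames],
            dtype=float,
        )


class PersonDetector(Protocol):
    def detect(self, image: np.ndarray) -> list[Box]: ...


class FaceDetector(Protocol):
    def detect(self, image: np.ndarray) -> list[Box]: ...


def _validate_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.size == 0:
        raise InputError("empty image")
    if arr.ndim == 3:
        if arr.shape[-1] not in (1, 3, 4):
            raise InputError(f"unsupported channel count {arr.shape[-1]}")
    elif arr.ndim != 2:
        raise InputError(f"image must be 2-D or 3-D, got ndim={arr.ndim}")
    return arr


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image[..., :3].mean(axis=-1)
    return image.astype(float)


def _foreground_mask(gray: np.ndarray, threshold: Optional[float]) -> Optional[np.ndarray]:
    if np.ptp(gray) == 0:
        return None  # uniform image: nothing to segment
    thr = threshold_otsu(gray) if threshold is None else threshold
    return gray < thr


class SilhouetteDetector:
    """Segmentation-based person detector for dark silhouettes on light ground.

    Thresholds the frame (Otsu unless a fixed threshold is given), labels
    connected foreground components and returns one box per component with
    at least ``min_area`` pixels.
    """

    def __init__(self, threshold: Optional[float] = None, min_area: int = 30) -> None:
        self.threshold = threshold
        self.min_area = min_area

    def detect(self, image: np.ndarray) -> list[Box]:
        gray = _to_gray(_validate_image(image))
        mask = _foreground_mask(gray, self.threshold)
        if mask is None:
            return []
        boxes = []
        for region in regionprops(label(mask)):
            if region.area < self.min_area:
                continue
            minr, minc, maxr, maxc = region.bbox
            boxes.append(Box(x=minc, y=minr, width=maxc - minc, height=maxr - minr))
        return boxes


class SilhouetteFaceDetector:
    """Head-block face detector for segmented silhouettes.

    Exploits the anthropometric layout of an upright figure: the head is a
    contiguous run of rows at the top of the silhouette that is markedly
    narrower than the torso.  Returns one face box whose height is the head
    height, or nothing when no narrow top run exists (e.g. occluded head,
    uniform blob).
    """

    def __init__(
        self,
        threshold: Optional[float] = None,
        min_area: int = 30,
        head_width_frac: float = 0.5,
    ) -> None:
        self.threshold = threshold
        self.min_area = min_area
        self.head_width_frac = head_width_frac

    def detect(self, image: np.ndarray) -> list[Box]:
        gray = _to_gray(_validate_image(image))
        mask = _foreground_mask(gray, self.threshold)
        if mask is None:
            return []
        regions = [r for r in regionprops(label(mask)) if r.area >= self.min_area]
        if not regions:
            return []
        # the walking subject dominates the frame: take the tallest region
        person = max(regions, key=lambda r: r.bbox[2] - r.bbox[0])
        minr, minc, maxr, maxc = person.bbox
        widths = mask[minr:maxr, minc:maxc].sum(axis=1)
        max_width = widths.max()
        head_rows = 0
        for w in widths:
            if 0 < w <= self.head_width_frac * max_width:
                head_rows += 1
            else:
                break
        person_height = maxr - minr
        if head_rows < 2 or head_rows > 0.45 * person_height:
            return []
        return [Box(x=minc, y=minr, width=maxc - minc, height=head_rows)]


def detect_person(image: np.ndarray, detector: Optional[PersonDetector] = None) -> Optional[Box]:
    """Detect the walking subject in one frame.

    When several candidate boxes exist the tallest is kept (the subject
    dominates a single-person protocol); returns ``None`` if nothing is
    detected.
    """
    arr = _validate_image(image)
    detector = detector if detector is not None else SilhouetteDetector()
    boxes = detector.detect(arr)
    if not boxes:
        return None
    return max(boxes, key=lambda b: b.height)


def detect_face(image: np.ndarray, detector: Optional[FaceDetector] = None) -> Optional[float]:
    """Detect the subject's face and return its pixel height, or ``None``."""
    arr = _validate_image(image)
    detector = detector if detector is not None else SilhouetteFaceDetector()
    boxes = detector.detect(arr)
    if not boxes:
        return None
    return float(max(boxes, key=lambda b: b.height).height)


def track_video(
    video_path,
    *,
    person_detector: Optional[PersonDetector] = None,
    face_detector: Optional[FaceDetector] = None,
    fps_override: Optional[float] = None,
    recording_id: Optional[str] = None,
) -> DetectionSeries:
    """Run the detectors over every frame of a video.

    fps is taken from container metadata when available, else it defaults to
    25 frames/s (the standard PAL rate); ``fps_override`` wins over both.
    Raises :class:`EmptyTrackError` when no frame contains a person.
    """
    path = Path(video_path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")
    person_detector = person_detector if person_detector is not None else SilhouetteDetector()
    face_detector = face_detector if face_detector is not None else SilhouetteFaceDetector()

    fps = fps_override
    if fps is None:
        try:
            meta = iio.immeta(path)
            fps = float(meta["fps"]) if "fps" in meta else None
        except Exception:
            fps = None
    if fps is None:
        fps = DEFAULT_FPS

    decoded = list(iio.imiter(path))
    if len(decoded) == 1 and decoded[0].ndim >= 3 and decoded[0].shape[-1] not in (1, 3, 4):
        # image-stack containers (e.g. multi-frame TIFF) decode as one array
        decoded = list(decoded[0])

    frames = []
    for i, frame in enumerate(decoded):
        box = detect_person(frame, person_detector)
        fh = detect_face(frame, face_detector)
        if box is not None and fh is not None and fh >= box.height:
            fh = None  # reject inconsistent face detection
        frames.append(
            FrameDetection(
                frame_index=i,
                person_height_px=None if box is None else float(box.height),
                person_width_px=None if box is None else float(box.width),
                face_height_px=fh,
            )
        )
    if not any(f.person_height_px is not None for f in frames):
        raise EmptyTrackError(f"no person detected in any frame of {path}")
    return DetectionSeries(
        recording_id=recording_id if recording_id is not None else path.stem,
        fps=float(fps),
        frames=frames,
    )


# ---------------------------------------------------------------------------
# detection CSV dialect: header `frame,person_h,person_w,face_h`, absent
# values as empty fields, recording metadata in leading `# key=value` lines.
# Floats are written with repr() so the round trip is bit-exact.
# ---------------------------------------------------------------------------

def _fmt(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))


def write_detection_csv(series: DetectionSeries, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# recording_id={series.recording_id}\n")
        fh.write(f"# fps={series.fps!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["frame", "person_h", "person_w", "face_h"])
        for f in series.frames:
            writer.writerow(
                [f.frame_index, _fmt(f.person_height_px), _fmt(f.person_width_px), _fmt(f.face_height_px)]
            )


def read_detection_csv(path) -> DetectionSeries:
    recording_id = Path(path).stem
    fps = DEFAULT_FPS
    body = io.StringIO()
    with open(path, "r") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if key.strip() == "recording_id":
                    recording_id = value.strip()
                elif key.strip() == "fps":
                    fps = float(value)
            else:
                body.write(line)
    body.seek(0)
    reader = csv.reader(body)
    header = next(reader)
    if header != ["frame", "person_h", "person_w", "face_h"]:
        raise InputError(f"unexpected detection CSV header: {header}")
    frames = []
    for row in reader:
        if not row:
            continue
        frames.append(
            FrameDetection(
                frame_index=int(row[0]),
                person_height_px=float(row[1]) if row[1] else None,
                person_width_px=float(row[2]) if row[2] else None,
                face_height_px=float(row[3]) if row[3] else None,
            )
        )
    return DetectionSeries(recording_id=recording_id, fps=fps, frames=frames)
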