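"""Exception hierarchy for the gait pipeline.

Every error raised by this package derives from :class:`GaitPipelineError`,
so batch drivers can catch one type, flag the recording, and continue.
"""


class GaitPipelineError(Exception):
    """Base class for all errors raised by frontgait."""


class InputError(GaitPipelineError, ValueError):
    """Malformed or out-of-contract input (wrong shape, non-positive value, ...)."""


class StageError(InputError):
    """A signal was passed to an operation that expects a different pipeline stage."""


class UnusableTrackError(GaitPipelineError):
    """A detection series with too few person detections to process."""


class EmptyTrackError(UnusableTrackError):
    """A video in which no frame contained a detected person."""


class MissingScaleError(GaitPipelineError):
    """No face height available (detected or supplied) for stature scaling."""


class DegenerateSignalError(GaitPipelineError):
    """A constant (zero-range / zero-fluctuation) signal where variation is required."""


class InsufficientEventsError(GaitPipelineError):
    """Too few gait events to compute stride phases or their statistics."""
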