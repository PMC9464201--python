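"""Exception hierarchy for the pipeline.

All errors raised by hvipipe derive from :class:`HviError` so callers can
catch pipeline failures without masking programming errors.
"""


class HviError(Exception):
    """Base class for all hvipipe errors."""


class ParameterError(HviError, ValueError):
    """A parameter or input violates a documented precondition."""


class VideoIOError(HviError, IOError):
    """A video file could not be read or written."""


class UnmeasurableProfileError(HviError):
    """An intensity profile has no measurable column (missing minima or
    a maximum on the profile edge)."""


class MeasurementFailure(HviError):
    """Too many frames of a clip were unmeasurable to report a width."""


class NoSegmentError(HviError):
    """No post-blink segment of the requested length exists in the clip."""


class DegenerateSignalError(HviError):
    """A constant signal: the autocorrelation normalization is undefined."""


class DesignError(HviError):
    """A statistical design is singular or otherwise unusable
    (e.g. only one crossover sequence present)."""
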