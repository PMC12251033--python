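"""Exception hierarchy.

Every malformed input raises a distinct, named error; nothing is silently
coerced. All exceptions derive from :class:`GaitCueError` so callers can
catch the package's failures with a single except clause.
"""


class GaitCueError(Exception):
    """Base class for all errors raised by this package."""


class MalformedHeaderError(GaitCueError):
    """A file's header (comment lines or column names) is not as expected."""


class NonMonotonicTimeError(GaitCueError):
    """Timestamps are not strictly increasing with uniform spacing."""


class AdcRangeError(GaitCueError):
    """An ADC sample lies outside the 10-bit range [0, 1023]."""


class UnknownMarkerError(GaitCueError):
    """A marker kind is not segment_start/segment_end, or markers repeat."""


class MissingMarkerError(GaitCueError):
    """An operation needs both pathway markers and one is absent."""


class InvalidIntervalError(GaitCueError):
    """An interval has end <= start, or an interval file row is malformed."""


class ChannelLengthError(GaitCueError):
    """Per-foot channel arrays have mismatched lengths."""


class ConfigError(GaitCueError):
    """A configuration object violates its declared invariants."""


class DegenerateInputError(GaitCueError):
    """Too few values, zero variance, or a non-positive mean where one is required."""


class StepOverlapError(GaitCueError):
    """A step is too short for a stance waveform to be synthesised without overlap."""
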