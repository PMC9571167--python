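"""Exception hierarchy shared across the package."""


class GaitError(Exception):
    """Base class for all gaitpolar errors."""


class ValidationError(GaitError, ValueError):
    """An input object violates a documented invariant."""


class FormatError(ValidationError):
    """A file does not match the expected column layout / schema."""


class TimingError(ValidationError):
    """Sample timestamps are not uniform at the declared sampling rate."""


class SignalError(GaitError):
    """A signal is unusable (e.g. no stance detected anywhere)."""


class NumericError(GaitError):
    """Non-finite values entered a numerical routine."""


class InsufficientCyclesError(GaitError):
    """Fewer complete gait cycles than the operation requires."""


class GeometryError(GaitError):
    """A polar curve segment is geometrically invalid (non-monotone angle)."""


class UndefinedIndexError(GaitError):
    """An index is undefined for the given input (e.g. zero denominator)."""


class UndefinedSlopeError(GaitError):
    """Tangent-line slope undefined (coincident crossing points)."""


class DetectionError(GaitError):
    """Event detection found no events on a required channel."""


class PairingError(GaitError):
    """Gait events cannot be paired into the required alternating order."""
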