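"""Exception hierarchy and warnings.

Every error raised by the package derives from :class:`CholspecError`,
so callers (and the CLI) can catch one type and map it to an exit code.
"""


class CholspecError(Exception):
    """Base class for all package errors."""


class ValidationError(CholspecError, ValueError):
    """An input violates a documented precondition or type invariant."""


class SpanError(ValidationError):
    """A target wavelength grid extends beyond the raw spectrum's span."""


class AlignmentError(ValidationError):
    """Two spectra (or a spectrum and a profile) are not on the same grid."""


class DegenerateDesignError(ValidationError):
    """The extinction profile is identically zero on the fitted band."""


class InsufficientDataError(ValidationError):
    """Too few points/pairs/groups for the requested computation."""


class OutOfRangeError(ValidationError):
    """A value lies outside the invertible range of a calibration curve."""


class UndefinedStatisticError(ValidationError):
    """The statistic is undefined for this input (constant series, zero mean)."""


class ParseError(CholspecError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class FitQualityWarning(UserWarning):
    """The calibration fit converged but describes the data poorly."""
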