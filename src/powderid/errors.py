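"""Exception hierarchy for powderid.

All data-level failures derive from :class:`PowderIdError` so callers (and the
CLI) can distinguish bad data (exit code 1) from usage errors (exit code 2).
"""


class PowderIdError(Exception):
    """Base class for all powderid data errors."""


class ParseError(PowderIdError):
    """A text input could not be parsed into the expected structure."""


class NonMonotoneGrid(ParseError):
    """2theta values are not strictly increasing."""


class NonUniformGrid(ParseError):
    """2theta spacing deviates too much from uniform; resample explicitly."""


class TooFewPoints(ParseError):
    """A diffractogram needs at least MIN_POINTS rows."""


class IOFailure(PowderIdError):
    """A file could not be read or written."""


class EmptyLibrary(PowderIdError):
    """A phase library contains no phases."""


class RangeError(PowderIdError):
    """A resampling target extends beyond the source grid."""


class DegenerateFit(PowderIdError):
    """The background design matrix is rank deficient."""


class GridMismatch(PowderIdError):
    """Two patterns do not share a common 2theta grid."""


class WindowTooLarge(PowderIdError):
    """Smoothing window exceeds the pattern length."""


class ZeroPattern(PowderIdError):
    """Cannot normalize a pattern whose maximum intensity is zero."""


class EmptyStandard(PowderIdError):
    """Peak matching requires a non-empty standard peak list."""


class ZeroDenominator(PowderIdError):
    """The CCS denominator (standard auto-correlation mass) is zero."""


class BadWeights(PowderIdError):
    """Mixture weights must be positive and sum to one."""


class ReflectionOutOfRange(UserWarning):
    """A reflection falls outside the simulation grid and is skipped."""
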