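"""Exception hierarchy.

All package errors derive from :class:`MinetError` so callers can catch one
base class; each also derives from the closest builtin so idiomatic
``except ValueError`` code keeps working.
"""


class MinetError(Exception):
    """Base class for all errors raised by minet."""


class InvalidParameterError(MinetError, ValueError):
    """A parameter (bandwidth, p-value, permutation count, ...) is out of range."""


class InvalidInputError(MinetError, ValueError):
    """Input data violates a precondition (empty sample, length mismatch, ...)."""


class ParseError(MinetError, ValueError):
    """A delimited matrix file could not be parsed; the message names the spot."""


class CalibrationError(MinetError, RuntimeError):
    """The permutation-null threshold calibration failed or is unusable."""


class DegenerateDesignError(MinetError, ValueError):
    """The least-squares design matrix is rank deficient; names collinear columns."""


class UndefinedMetricError(MinetError, ValueError):
    """A requested metric is undefined for the given data (e.g. R^2 of a constant)."""
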