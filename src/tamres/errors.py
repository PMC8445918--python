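"""Exception hierarchy for tamres.

All package-specific failures derive from :class:`TamresError` so callers can
catch the whole family with one clause while tests pin down the precise kind.
"""


class TamresError(Exception):
    """Base class for all tamres errors."""


class InvalidParameterError(TamresError, ValueError):
    """A model parameter violates its domain (sign, range, or count)."""


class InvalidStateError(TamresError, ValueError):
    """A cell-state vector has a negative component or wrong shape."""


class InvalidTargetError(TamresError, ValueError):
    """An inhibition target name is not one of the four inhibitable reactions."""


class SchemaError(TamresError, ValueError):
    """A dataset or config is structurally malformed; the message names the field."""


class AlignmentError(TamresError, ValueError):
    """Two observation sets do not share identical labels/ordering."""


class IntegrationError(TamresError, RuntimeError):
    """The ODE solver failed or the state blew up; the message names the interval."""


class InsufficientHorizonError(TamresError, ValueError):
    """A trajectory is too short for the requested observable."""


class InsufficientSampleError(TamresError, ValueError):
    """Too few paired values for the rank test."""


class UndefinedSensitivityError(TamresError, ArithmeticError):
    """The mean growth rate was non-positive, so its log-sensitivity is undefined."""
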