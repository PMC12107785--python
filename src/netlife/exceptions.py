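"""Exception hierarchy used across the package."""


class NetlifeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NetlifeError, ValueError):
    """An argument violates a documented precondition."""


class CoverageError(NetlifeError, LookupError):
    """Required life-table coverage (a year or an age) is missing."""


class DegenerateDataError(NetlifeError, ValueError):
    """Input data carry no usable signal (e.g. all-zero death counts)."""


class FittingError(NetlifeError, RuntimeError):
    """A model fit failed to converge."""


class InsufficientDataError(NetlifeError, ValueError):
    """Too few usable observations for the requested fit."""


class InversionError(NetlifeError, ArithmeticError):
    """A relational-model transform could not be inverted on (0, 1)."""


class IncompleteFollowupError(NetlifeError, ValueError):
    """A record is censored before the requested horizon."""


class InvalidWeightsError(NetlifeError, ValueError):
    """Standardization weights are not a valid weight set."""


class NoIntersectionError(NetlifeError, ValueError):
    """A reference survival never crosses the sweep curve."""


class ParseError(NetlifeError, ValueError):
    """A file could not be parsed; carries the offending location."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
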