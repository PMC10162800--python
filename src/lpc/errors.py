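"""Exception hierarchy shared across the package."""


class LPCError(Exception):
    """Base class for all package errors."""


class FormatError(LPCError):
    """On-disk data is missing metadata or is internally inconsistent."""


class ShapeError(LPCError, ValueError):
    """Array dimensions do not match the declared geometry."""


class ParameterError(LPCError, ValueError):
    """A parameter violates an operation's precondition."""


class EstimationError(LPCError):
    """An estimator cannot produce a result from the given data."""


class UndefinedResultError(LPCError):
    """A statistic is undefined for the given sample (e.g. empty input)."""
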