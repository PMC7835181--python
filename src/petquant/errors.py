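"""Exception hierarchy for petquant."""


class PetQuantError(Exception):
    """Base class for all petquant errors."""


class ScheduleError(PetQuantError):
    """Invalid frame schedule (overlap, non-monotone, bad token)."""


class FormatError(PetQuantError):
    """Malformed delimited-text input."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(PetQuantError):
    """Input values violate a documented precondition."""


class StateError(PetQuantError):
    """Operation inconsistent with object state (e.g. double decay correction)."""


class FitError(PetQuantError):
    """Curve fit failed to converge.

    ``best`` carries the best attempt found (parameter vector or fitted
    object), so callers can inspect or fall back to a non-parametric method.
    """

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class DegenerateInputError(FitError):
    """Data carry no information for the requested fit (e.g. all zeros)."""
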