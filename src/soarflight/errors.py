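"""Exception types shared across the package."""


class SoarflightError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SoarflightError, ValueError):
    """An input violates a documented precondition."""


class OutOfDomainError(SoarflightError):
    """A query point fell outside a gridded field.

    Carries the offending indices/points when known so callers (e.g. the
    path simulator, which treats domain exit as a termination signal) can
    decide how to react.
    """

    def __init__(self, message, indices=None):
        super().__init__(message)
        self.indices = indices


class RankDeficientError(SoarflightError, ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = columns


class InsufficientDataError(SoarflightError, ValueError):
    """Not enough usable records for the requested fit."""
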