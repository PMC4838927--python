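"""Exception types shared across the package."""


class AlgalinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AlgalinkError, ValueError):
    """A configuration value is missing, unknown, or out of range."""


class OutOfDomainError(AlgalinkError, ValueError):
    """A point lies outside the micro-aquarium bounding box."""


class UndefinedRatioError(AlgalinkError, ZeroDivisionError):
    """The group TM ratio is undefined because both group sums are zero."""


class InsufficientOscillationError(AlgalinkError, ValueError):
    """Too few illumination flips to measure an oscillation period."""


class UnmatchedFlipsError(AlgalinkError, ValueError):
    """Flip sequences of the two dishes cannot be paired one-to-one."""

    def __init__(self, message, orphans=()):
        super().__init__(message)
        self.orphans = tuple(orphans)
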