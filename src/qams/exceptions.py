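"""Exception hierarchy shared across the package."""


class QamsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QamsError):
    """A compound, marker, model or schema element is missing or inconsistent."""


class DomainError(QamsError, ValueError):
    """An input value lies outside the mathematical domain of an operation
    (nonpositive concentration or area, log of zero, nonpositive divisor)."""


class FitError(QamsError):
    """A calibration fit cannot be performed (too few points, degenerate design)."""
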