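"""Exception hierarchy shared across the package."""


class AnthroError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AnthroError, ValueError):
    """A config file, column mapping or CLI option is unusable."""


class DataError(AnthroError, ValueError):
    """Input data violate a structural invariant (e.g. duplicate LMS keys)."""


class OutOfRangeError(AnthroError, ValueError):
    """A lookup key falls outside the growth reference's tabulated range."""

    def __init__(self, message: str, valid_range: tuple[float, float] | None = None):
        super().__init__(message)
        self.valid_range = valid_range


class DomainError(AnthroError, ValueError):
    """An argument is outside the mathematical domain of a transform."""


class UnclassifiableError(AnthroError, ValueError):
    """A child-visit cannot be assigned a CIAF category (missing z-scores)."""
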