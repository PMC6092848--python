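"""Exception hierarchy shared across the package."""


class APCError(Exception):
    """Base class for all package errors."""


class ValidationError(APCError, ValueError):
    """A data record violates its invariants (message names the offending record)."""


class ConfigurationError(APCError, ValueError):
    """A scheme, reference, or configuration value is inconsistent or unusable."""


class DomainError(APCError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class FitError(APCError, RuntimeError):
    """Model fitting failed in a way that should be impossible under the constraints."""
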