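"""Exception hierarchy shared across the package."""


class SoiolError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SoiolError, ValueError):
    """A physically or mathematically inadmissible input to an optical formula.

    Raised e.g. when the equivalent-corneal-power denominator goes
    non-positive, or when the effective lens position reaches the retina.
    """


class InputValidationError(SoiolError, ValueError):
    """A record or field failed range/schema validation."""


class ConfigError(SoiolError, ValueError):
    """A configuration file or coefficient set is unusable."""
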