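"""Exception types shared across the package."""

__all__ = ["FabrykitError", "ConfigurationError", "DataError", "ModelError"]


class FabrykitError(Exception):
    """Base class for package errors."""


class ConfigurationError(FabrykitError):
    """A config field is missing, malformed, or out of range."""


class DataError(FabrykitError):
    """Input data violate a structural contract (e.g. male allele count 2)."""


class ModelError(FabrykitError):
    """A model cannot be fitted on the given data (separation, constant outcome...)."""
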