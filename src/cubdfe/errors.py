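"""Exception types shared across the package."""


class CubdfeError(Exception):
    """Base class for package-specific errors."""


class DomainError(CubdfeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ModelInvalidError(CubdfeError, ValueError):
    """A parameter combination implies an invalid probability model
    (e.g. a negative monomorphic-class probability)."""


class ConfigError(CubdfeError, ValueError):
    """Inconsistent or malformed configuration."""


class DataError(CubdfeError, ValueError):
    """Malformed or insufficient input data."""
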