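"""Exception hierarchy shared across the package."""


class RetinotopoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RetinotopoError):
    """A required configuration value is missing or invalid."""


class DomainError(RetinotopoError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class GeometryError(RetinotopoError, ValueError):
    """A polygon or point fails a geometric precondition."""


class FrameError(RetinotopoError):
    """An operation requiring the canonical frame received raw coordinates."""


class DataError(RetinotopoError):
    """A cell table violates the data contract (missing fields, bad rows)."""
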