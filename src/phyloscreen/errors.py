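"""Exception hierarchy shared across the package."""


class PhyloscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhyloscreenError, ValueError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(PhyloscreenError, ValueError):
    """A table is missing required columns or violates its schema."""


class NormalizationError(PhyloscreenError, ValueError):
    """Raw reading could not be normalized to its control."""


class InsufficientDataError(PhyloscreenError, ValueError):
    """Too few observations for the requested statistic."""


class StageError(PhyloscreenError, RuntimeError):
    """A pipeline stage failed or its prerequisites are missing."""
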