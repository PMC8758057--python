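"""Exception hierarchy shared across the package."""


class BladderPhenoError(ValueError):
    """Base class for all package-specific errors."""


class ScoringError(BladderPhenoError):
    """A subscale could not be scored (typically a missing item)."""


class ValidationError(BladderPhenoError):
    """An answer or input table violates the item schema."""


class ConfigurationError(BladderPhenoError):
    """A composite/pipeline configuration is malformed."""


class DegenerateFeatureError(BladderPhenoError):
    """A feature has zero variance where a z-scale is required."""
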