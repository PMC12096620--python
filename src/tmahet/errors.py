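"""Exception types shared across the pipeline stages."""


class TmahetError(Exception):
    """Base class for all package errors."""


class ValidationError(TmahetError):
    """A configuration or specification object failed validation.

    The message always names the offending field.
    """


class SchemaError(TmahetError):
    """An input table is missing required columns or carries bad values."""


class ConfigError(TmahetError):
    """A run configuration is internally inconsistent."""
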