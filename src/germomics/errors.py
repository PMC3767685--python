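"""Exception hierarchy for the pipeline."""


class GermomicsError(Exception):
    """Base class for all package errors."""


class FormatError(GermomicsError):
    """A file or header does not match the expected on-disk layout."""


class ValidationError(GermomicsError):
    """Data violate an invariant (negative value, unknown group, ...)."""


class ConfigError(GermomicsError):
    """A configuration value is inconsistent or out of range."""


class UsageError(GermomicsError):
    """An operation was called outside its documented domain."""
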