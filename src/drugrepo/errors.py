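"""Exception hierarchy shared across the pipeline stages."""


class DrugRepoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DrugRepoError):
    """A configuration value is missing, malformed, or out of range."""


class ValidationError(DrugRepoError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A table is missing mandatory columns or has an unexpected header."""


class ClassificationError(ValidationError):
    """Free text could not be mapped onto a closed vocabulary."""


class EmptyInputError(ValidationError):
    """An operation received no usable rows at all."""
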