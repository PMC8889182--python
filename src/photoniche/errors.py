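"""Exception hierarchy shared by all analysis stages."""


class PhotonicheError(Exception):
    """Base class for all package errors."""


class DomainError(PhotonicheError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class DegenerateDataError(PhotonicheError, ValueError):
    """Input data are too small or too degenerate to support the computation."""


class SchemaError(PhotonicheError, ValueError):
    """A table does not match its required column schema."""


class ConfigError(PhotonicheError, ValueError):
    """Inconsistent configuration (e.g. species mismatch between inputs)."""


class PipelineError(PhotonicheError, RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
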