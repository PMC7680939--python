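"""Exception types used across the pipeline."""


class MetgainError(Exception):
    """Base class for package errors."""


class ConfigurationError(MetgainError, ValueError):
    """Invalid configuration (block geometry, model order, option clash)."""


class ValidationError(MetgainError, ValueError):
    """Input data violates a structural invariant."""


class ParseError(MetgainError, ValueError):
    """A file could not be parsed; message names the offending line."""
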