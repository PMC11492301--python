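"""Exception hierarchy shared across the package."""


class MlcQaError(Exception):
    """Base class for all mlcqa errors."""


class FormatError(MlcQaError, ValueError):
    """A file does not conform to its documented dialect."""


class ValidationError(MlcQaError, ValueError):
    """Structurally valid input violates a domain invariant."""


class ConfigurationError(MlcQaError, ValueError):
    """A parameter combination is inconsistent or physically meaningless."""
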