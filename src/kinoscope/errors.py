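class KinoscopeError(Exception):
    """Base class for all package errors."""


class ValidationError(KinoscopeError, ValueError):
    """Malformed or internally inconsistent input data."""


class ConfigError(KinoscopeError, ValueError):
    """Invalid configuration values."""
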