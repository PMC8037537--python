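"""Exception types shared across the package."""


class CernaWeaverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CernaWeaverError):
    """A configuration value is out of range or internally inconsistent."""


class ValidationError(CernaWeaverError):
    """An input record violates a contract (bad biotype, empty sequence, ...)."""
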