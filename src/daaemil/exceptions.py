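"""Package-wide error types."""


class ConfigurationError(ValueError):
    """An invalid configuration object or option combination."""


class DomainError(ValueError):
    """Input violates a documented precondition."""


class VolumeIOError(IOError):
    """A volume file could not be read or written."""
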