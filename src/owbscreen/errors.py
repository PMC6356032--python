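"""Exception hierarchy for the OWB screening model."""


class OWBError(Exception):
    """Base class for all owbscreen errors."""


class RegistryError(OWBError):
    """Parameter registry could not be loaded or a constant is missing/invalid."""


class DomainError(OWBError):
    """An operation was called outside its domain (bad scenario, bad inputs)."""


class ConfigError(OWBError):
    """A run configuration document failed validation."""
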