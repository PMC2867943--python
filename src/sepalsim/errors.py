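"""Exception hierarchy shared across the package."""


class SepalSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SepalSimError):
    """A configuration value or file is invalid."""


class InvalidStateError(SepalSimError):
    """An operation was applied to a cell in an incompatible phase."""


class RuntimeLimitError(SepalSimError):
    """A simulation exceeded its safety cap without terminating."""
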