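"""Exception hierarchy shared by all pipeline stages."""


class SeafloodError(Exception):
    """Base class for all package errors."""


class InputError(SeafloodError, ValueError):
    """A data value or table violates a stage's preconditions."""


class ConfigError(SeafloodError, ValueError):
    """A configuration field is invalid; the message names the field."""
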