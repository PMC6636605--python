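"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is invalid (names the offending field)."""


class InputError(ValueError):
    """An input object violates a precondition of an operation."""
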