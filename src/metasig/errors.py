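"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A configuration value is out of its admissible range."""


class InputError(ValueError):
    """An input table or data structure violates a stage precondition."""
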