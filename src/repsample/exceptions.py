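"""Exception types."""


class ConfigurationError(ValueError):
    """Invalid configuration: bad weights, unmapped labels, out-of-range rates."""


class InputDataError(ValueError):
    """Invalid input data: unknown category labels, missing schema columns."""
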