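"""Exception types raised by gimda."""


class GimdaError(ValueError):
    """Invalid input data or configuration."""
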