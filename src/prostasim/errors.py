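"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration or input table; the message names the offending key/row."""


class PairingError(ValueError):
    """Paired screened/unscreened life histories do not share a disease course."""
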