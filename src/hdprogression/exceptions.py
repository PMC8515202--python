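class ConfigurationError(ValueError):
    """Invalid generator or model configuration; the message names the field."""


class FitError(RuntimeError):
    """Model fitting cannot proceed (e.g. unidentifiable shifts)."""
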