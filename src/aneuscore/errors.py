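class ConfigurationError(ValueError):
    """A parameter value violates the documented constraints."""


class EmptyResultError(RuntimeError):
    """An operation removed every cell or gene; downstream steps cannot run."""
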