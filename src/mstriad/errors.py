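"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """The sample design or run configuration is inconsistent with the data."""


class ValidationError(ValueError):
    """An input table violates a structural contract (duplicates, bad shapes)."""
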