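"""Error types distinguishing bad model configuration from bad runtime inputs."""


class ConfigError(ValueError):
    """A parameter set or scenario configuration is invalid."""


class InputError(ValueError):
    """A runtime input (cohort, individual state, argument) is invalid."""
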