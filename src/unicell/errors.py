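"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is missing, unknown, or out of range."""


class UsageError(ValueError):
    """An operation was called on a state the model forbids."""


class SimulationStateError(RuntimeError):
    """Internal invariant violated (e.g. executing a dead organism)."""
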