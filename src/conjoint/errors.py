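"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(ValueError):
    """A configuration value or key is invalid."""


class EngineError(RuntimeError):
    """The ODE integrator failed; carries the last valid state when known."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state
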