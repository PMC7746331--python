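"""Exception hierarchy shared across the package."""


class MrkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MrkitError):
    """A configuration problem: missing column, bad parameter file, unknown method."""


class ValidationError(MrkitError, ValueError):
    """Input data violates an invariant (non-positive SE, zero exposure beta, ...)."""


class InsufficientInstrumentsError(MrkitError, ValueError):
    """A method was asked to run with fewer instruments than it supports."""

    def __init__(self, method: str, required: int, got: int):
        self.method = method
        self.required = required
        self.got = got
        super().__init__(
            f"{method} requires at least {required} instruments, got {got}"
        )
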