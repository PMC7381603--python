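"""Exception types shared across the pipeline."""


class IsoringError(Exception):
    """Base class for all package errors."""


class ValidationError(IsoringError, ValueError):
    """Input table violates a schema or structural invariant."""


class DomainError(IsoringError, ValueError):
    """Numeric argument outside the physically meaningful domain."""


class InsufficientDataError(IsoringError, ValueError):
    """Too few observations for the requested fit."""


class ConvergenceError(IsoringError, RuntimeError):
    """Optimizer failed to converge; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
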