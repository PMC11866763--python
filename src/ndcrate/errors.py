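"""Exception types shared across the package."""


class NdcrateError(Exception):
    """Base class for all package errors."""


class ValidationError(NdcrateError, ValueError):
    """An input violates a model invariant; the message names it."""


class ConvergenceError(NdcrateError, RuntimeError):
    """A numerical procedure failed to converge; carries diagnostics."""
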