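"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class NumericalError(RuntimeError):
    """Raised when an evolution produces non-finite values."""
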