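"""Exception types raised across the package."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class NumericalFailureError(RuntimeError):
    """The solver produced non-finite values or an inconsistent transform."""
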