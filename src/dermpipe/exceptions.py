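"""Package-wide error types."""


class DomainError(ValueError):
    """An input violates an operation's stated precondition."""


class DegenerateInputError(DomainError):
    """The input is degenerate (e.g. constant image) and the quantity is undefined."""
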