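"""Package-wide error and warning types."""


class InvalidInputError(ValueError):
    """Raised when an operation's input violates its preconditions."""


class QuenchBindWarning(UserWarning):
    """Non-fatal data-quality signal (rejected points, boundary peaks,
    out-of-range inverse predictions, negative assay results)."""
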