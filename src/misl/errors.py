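"""Exception types shared across the package."""


class MislError(Exception):
    """Base class for all package errors."""


class FormatError(MislError):
    """An input file violates its format contract (missing column, bad row)."""


class ValidationError(MislError):
    """An in-memory table or argument violates an invariant."""
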