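class FamprsError(Exception):
    """Base class for all famprs errors."""


class FormatError(FamprsError):
    """A file does not conform to the expected layout (missing columns, bad tokens)."""


class ValidationError(FamprsError):
    """Structurally well-formed input violates a domain invariant."""
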