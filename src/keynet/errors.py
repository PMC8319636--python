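"""Exception hierarchy shared across the pipeline stages."""


class KeynetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KeynetError, ValueError):
    """A file or table does not conform to its declared dialect."""


class DomainError(KeynetError, ValueError):
    """An argument violates a stated precondition (bounds, emptiness)."""
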