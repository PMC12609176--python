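"""Exception taxonomy: every user-facing failure maps to one of these."""


class PolysiteError(Exception):
    """Base class for all package errors."""


class FormatError(PolysiteError):
    """Input file could not be parsed in the expected format."""


class EmptyInputError(PolysiteError):
    """Input contained no usable records (e.g. waters only, empty chain)."""


class ConsistencyError(PolysiteError):
    """Cross-input invariant violated (length mismatch, bad shapes)."""


class SchemaError(PolysiteError):
    """Array container missing required datasets or metadata."""
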