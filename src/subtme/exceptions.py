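"""Exception hierarchy shared by all stages."""


class SubtmeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SubtmeError, ValueError):
    """An input file does not conform to its declared on-disk format."""


class ValidationError(SubtmeError, ValueError):
    """Inputs are well-formed but violate a documented invariant."""


class EmptyResultError(SubtmeError, RuntimeError):
    """An operation removed or excluded every record it was given."""


class EmptySignatureError(SubtmeError, RuntimeError):
    """No gene passed the signature-score cutoff for a cell subtype."""
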