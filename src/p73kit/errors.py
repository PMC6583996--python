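"""Exception hierarchy shared across modules."""


class P73KitError(Exception):
    """Base class for all package errors."""


class FormatError(P73KitError, ValueError):
    """A file could not be parsed (missing columns, malformed row, ...)."""


class ValidationError(P73KitError, ValueError):
    """Parsed data violates a domain invariant."""


class GeometryError(ValidationError):
    """Exon/interval geometry makes the requested junction impossible."""


class UsageError(P73KitError, ValueError):
    """An operation was called with arguments outside its contract."""


class ModeError(UsageError):
    """A matrix is in the wrong mode (counts vs TPM) for the operation."""
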