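"""Exception hierarchy shared across the package."""


class EzquantError(Exception):
    """Base class for all package errors."""


class FormatError(EzquantError):
    """A file does not conform to the documented dialect (shape, layout)."""


class ParseError(EzquantError):
    """A cell or token could not be interpreted."""


class ValidationError(EzquantError):
    """Data parsed fine but violates a domain invariant."""


class DomainError(EzquantError):
    """An operation was called on inputs outside its domain (e.g. empty mask)."""
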