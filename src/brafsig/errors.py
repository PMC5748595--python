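"""Exception hierarchy for brafsig.

All package errors derive from :class:`BrafSigError` so callers can catch
one base class; specific subclasses mark validation vs. parsing failures.
"""


class BrafSigError(ValueError):
    """Base class for all brafsig errors."""


class ValidationError(BrafSigError):
    """An input object violates a structural invariant (duplicates,
    non-finite values, missing genes, degenerate classes, ...)."""


class ParseError(BrafSigError):
    """A file could not be parsed into the expected tabular form."""
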