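"""Exception hierarchy."""

from __future__ import annotations

__all__ = ["FernBarcodeError", "ParseError", "ValidationError", "EmptyInputError"]


class FernBarcodeError(Exception):
    """Base class for all package errors."""


class ParseError(FernBarcodeError, ValueError):
    """A file or record could not be parsed."""


class ValidationError(FernBarcodeError, ValueError):
    """Input violates a documented invariant."""


class EmptyInputError(ParseError):
    """An input file contained no records."""
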