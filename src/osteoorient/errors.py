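"""Exception hierarchy.

All package errors derive from :class:`OsteoOrientError` so callers can
catch everything with one clause; the concrete classes also inherit the
closest builtin (``ValueError``, ``KeyError``) for idiomatic handling.
"""


class OsteoOrientError(Exception):
    """Base class for all errors raised by osteoorient."""


class ValidationError(OsteoOrientError, ValueError):
    """An input violates a documented precondition (shape, range, type)."""


class DegenerateInputError(OsteoOrientError, ValueError):
    """The input is formally valid but the quantity is undefined on it
    (e.g. a constant image has no angular spectrum)."""


class DegenerateRegionError(OsteoOrientError, ValueError):
    """A labeled region is too small or too thin for a stable shape
    measurement."""


class LabelNotFoundError(OsteoOrientError, KeyError):
    """A requested cell label is absent from a mask."""


class PlacementError(OsteoOrientError, RuntimeError):
    """Synthetic cells could not be placed without overlap within the
    retry budget."""


class EmptyInputError(OsteoOrientError, ValueError):
    """A collection-valued input (mask, track set) contains no items."""


class FormatError(OsteoOrientError, ValueError):
    """A file on disk could not be parsed as the expected format."""
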