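"""Exception hierarchy.

All errors raised by the package derive from :class:`SemirigidError`, which
itself derives from ``ValueError`` so that generic callers can catch either.
"""


class SemirigidError(ValueError):
    """Base class for all errors raised by :mod:`semirigid`."""


class InsufficientFramesError(SemirigidError):
    """A trajectory has too few frames for the requested operation."""


class SelectionError(SemirigidError):
    """An atom selection is empty or too small."""


class DimensionMismatchError(SemirigidError):
    """Array shapes of matrix / assignment / membership inputs disagree."""


class FormatError(SemirigidError):
    """A file does not parse as the declared format."""


class ParameterError(SemirigidError):
    """A parameter is outside its admissible range."""
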