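"""Exception hierarchy.

All package errors derive from :class:`RestoselectError` so callers can
catch everything with one clause; each subclass also derives from the
closest builtin (``ValueError``/``OSError``) for idiomatic handling.
"""


class RestoselectError(Exception):
    """Base class for all errors raised by restoselect."""


class SchemaError(RestoselectError, ValueError):
    """A table or file does not match the expected column schema."""


class LabelError(RestoselectError, ValueError):
    """A class label is outside the closed five-class label set."""


class DuplicationError(RestoselectError, ValueError):
    """A supposedly unique identifier occurs more than once."""


class ImageIOError(RestoselectError, OSError):
    """An image file could not be read or is degenerate."""


class DimensionError(RestoselectError, ValueError):
    """An image or crop/grid dimension constraint is violated."""


class SplitError(RestoselectError, ValueError):
    """A patient-level split or fold plan cannot be constructed."""


class FitnessError(RestoselectError, ValueError):
    """A feature mask or fitness evaluation is invalid."""


class ConfigError(RestoselectError, ValueError):
    """A configuration object violates one of its invariants."""
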