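"""Exception hierarchy.

All errors raised by extruflow derive from :class:`ExtruflowError`, so callers
can catch the package's failures with a single except clause while still
distinguishing bad numbers (:class:`InvalidInputError`) from bad files
(:class:`ParseError`) and from datasets too small to support an operation
(:class:`InsufficientDataError`).
"""


class ExtruflowError(Exception):
    """Base class for all extruflow errors."""


class InvalidInputError(ExtruflowError, ValueError):
    """A physical quantity is outside its valid domain (e.g. pressure <= 0)."""


class InsufficientDataError(ExtruflowError, ValueError):
    """Too few observations for the requested estimate or fit."""


class ParseError(ExtruflowError, ValueError):
    """A file does not conform to the declared dialect."""


class MismatchError(ExtruflowError, ValueError):
    """Two inputs that must share keys (e.g. pressures) do not."""


class CalibrationError(ExtruflowError, RuntimeError):
    """An image operation was requested on an uncalibrated frame."""


class RenderError(ExtruflowError, ValueError):
    """A synthetic frame cannot be rendered with the given geometry."""
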