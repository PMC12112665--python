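"""Exception hierarchy.

Every error painface raises deliberately derives from :class:`PainfaceError`
so callers can catch the whole family; the subclasses mirror the failure
modes of the pipeline (bad arguments, malformed files, inconsistent
configuration, degenerate geometry).
"""


class PainfaceError(Exception):
    """Base class for all painface errors."""


class InvalidArgumentError(PainfaceError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(PainfaceError):
    """A landmark or config file could not be parsed."""


class SchemaError(PainfaceError):
    """Parsed data violates a structural invariant (e.g. wrong point count)."""


class ConfigError(PainfaceError):
    """Zone / calibration / weight configuration is inconsistent."""


class DegenerateGeometryError(PainfaceError):
    """Geometry does not admit the requested operation (e.g. coincident eyes)."""
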