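"""Exception hierarchy for ciliapol.

All package errors derive from :class:`CiliapolError` so callers can catch
one base class at pipeline level while tests assert on specific subclasses.
"""


class CiliapolError(Exception):
    """Base class for all ciliapol errors."""


class InvalidParameterError(CiliapolError, ValueError):
    """A parameter violates a documented precondition."""


class DegeneratePolygonError(CiliapolError, ValueError):
    """Polygon has (numerically) zero area or fewer than three vertices."""


class SelfIntersectingPolygonError(CiliapolError, ValueError):
    """Polygon edges cross; area/centroid would be meaningless."""


class AliasingError(InvalidParameterError):
    """Requested beat frequency is at or above the Nyquist limit."""


class UndefinedStatisticError(CiliapolError, ValueError):
    """A statistic is undefined for the given input (e.g. zero vector)."""


class ParseError(CiliapolError, ValueError):
    """A file violated the expected schema; message lists offending rows."""


class MissingMetadataError(CiliapolError, ValueError):
    """A required metadata field (e.g. fps) is absent; never silently default."""


class PipelineError(CiliapolError, RuntimeError):
    """A pipeline stage failed; message carries stage name and context."""
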