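"""Exception hierarchy.

Every error raised on purpose by the package derives from :class:`InvasimError`
so callers (and the CLI) can distinguish validation problems (exit code 1)
from numerical failures (exit code 2).
"""


class InvasimError(Exception):
    """Base class for all package errors."""


class FormatError(InvasimError):
    """A file does not conform to its declared format."""


class ParameterError(InvasimError, ValueError):
    """An argument value is outside its admissible range."""


class DomainError(InvasimError, ValueError):
    """A coordinate falls outside the domain it must lie in."""


class GeometryError(InvasimError):
    """Invalid or degenerate geometry (polygons, triangles)."""


class StateError(InvasimError):
    """An object is not in the state the operation requires."""


class DimensionError(InvasimError, ValueError):
    """Array shapes or lengths are inconsistent."""


class CoefficientError(InvasimError, ValueError):
    """A model coefficient violates its sign/shape contract."""


class NumericalError(InvasimError):
    """Iterative solver failure or solution blow-up."""


class ConfigError(InvasimError):
    """Scenario configuration is missing or inconsistent."""


class DegeneracyError(InvasimError):
    """Sample set or moment matrix too degenerate for the request."""
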