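"""Package exception hierarchy."""


class FlextopError(Exception):
    """Base class for all package errors."""


class SingularGeometryError(FlextopError):
    """Two interacting particles coincide (pair distance zero)."""


class IntegrationError(FlextopError):
    """Non-finite force or gradient encountered during dynamics."""


class PlacementError(FlextopError):
    """Initial particle placement failed after the allowed restarts."""


class UndefinedOverlapError(FlextopError):
    """Overlap metric requested between two empty fields."""


class DegenerateGeometryError(FlextopError):
    """Too few or collinear points for a geometric operation."""


class ParseError(FlextopError):
    """Malformed input file."""


class LookupErrorAtom(FlextopError):
    """Atom name missing from the nonbonded parameter table."""
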