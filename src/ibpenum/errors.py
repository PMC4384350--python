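"""Exception hierarchy for the iBP toolkit."""


class IBPError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(IBPError, ValueError):
    """Raised for inputs that cannot describe a valid geometric object
    (non-positive distances, degenerate bond angles, empty domains)."""


class DegenerateGeometryError(IBPError, ValueError):
    """Raised when a geometric construction collapses (collinear sphere
    centers, coplanar anchors, singular linear systems)."""


class InfeasibleGeometryError(IBPError, ValueError):
    """Raised when a set of distances is not realizable in three
    dimensions (|cos| > 1 in the torsion-distance relation)."""


class ConfigurationError(IBPError, ValueError):
    """Raised for invalid run configurations: unknown atoms, missing
    covalent-table entries, unsupported residues."""


class InfeasibleOrderError(IBPError, ValueError):
    """Raised when a vertex order lacks the distances required to
    discretize the search (a vertex without three constrained
    predecessors)."""
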