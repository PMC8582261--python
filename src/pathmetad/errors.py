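"""Exception hierarchy.

All package errors derive from :class:`PathMetaDError` so callers can catch
one base class; subclasses mirror the distinct failure contracts of the API
(parse/format problems, degenerate geometry, bad parameters, ...).
"""


class PathMetaDError(Exception):
    """Base class for all pathmetad errors."""


class ParseError(PathMetaDError):
    """A file could not be parsed; message carries the offending line number."""


class FormatError(PathMetaDError):
    """A file parsed but violates the format contract (e.g. model atom-count mismatch)."""


class DegenerateFitError(PathMetaDError):
    """Superposition impossible: fewer than 3 fit atoms or a collinear set."""


class SelectionError(PathMetaDError):
    """An atom selection is empty, out of bounds or not resolvable."""


class DimensionError(PathMetaDError):
    """Mismatched atom counts / array shapes between two inputs."""


class InsufficientDataError(PathMetaDError):
    """Not enough frames/samples for the requested analysis."""


class ParameterError(PathMetaDError):
    """A parameter is outside its documented domain."""


class PropagationError(PathMetaDError):
    """Dynamics produced non-finite coordinates, forces or CVs."""


class PathGapError(PathMetaDError):
    """Frame selection found no frame inside the spacing band across a gap."""


class DegeneratePathError(PathMetaDError):
    """Reference path contains coincident consecutive frames (zero spacing)."""


class EmptyBiasError(PathMetaDError):
    """A free-energy estimate was requested from a bias with no hills."""


class GridResolutionError(PathMetaDError):
    """A profile bin contains no grid nodes; a finer grid is required."""


class TopologyError(PathMetaDError):
    """Required covalent context is missing (e.g. donor without attached hydrogen)."""


class RadiusTableError(PathMetaDError):
    """No van der Waals radius known for an element."""


class ConstructionError(PathMetaDError):
    """A synthetic fixture could not be built with the requested properties."""


class NumericError(PathMetaDError):
    """A numeric quantity that must be finite was not."""
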