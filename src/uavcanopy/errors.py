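"""Exception hierarchy for the phenotyping pipeline.

Every stage raises a subclass of :class:`UavCanopyError`, so callers can
catch pipeline failures without masking programming errors.
"""


class UavCanopyError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(UavCanopyError, ValueError):
    """A parameter violates its documented precondition."""


class EmptyCloudError(UavCanopyError):
    """A point cloud is empty (or the scene it samples has zero area)."""


class AlignmentError(UavCanopyError):
    """Two grids that must share geometry (cell size, origin, shape) do not."""


class EmptyCanopyError(UavCanopyError):
    """No foreground canopy found near a plant center.

    Carries the offending ``plant_id`` when known.
    """

    def __init__(self, message: str, plant_id=None):
        super().__init__(message)
        self.plant_id = plant_id


class DegenerateCanopyError(UavCanopyError):
    """Fewer than three scan-line intersections: perimeter/area undefined."""

    def __init__(self, message: str, plant_id=None, n_points: int = 0):
        super().__init__(message)
        self.plant_id = plant_id
        self.n_points = n_points


class InvalidPolygonError(UavCanopyError):
    """A polygon has too few vertices or covers no grid cell centers."""


class NumericDomainError(UavCanopyError):
    """An index formula was evaluated outside its numeric domain."""


class InsufficientDataError(UavCanopyError):
    """Too few observations for the requested fit."""


class SingularFitError(UavCanopyError):
    """The fit's design is singular (e.g. all predictors zero or constant)."""


class SchemaError(UavCanopyError):
    """A table or file is missing required columns or is malformed."""


class MissingInputError(UavCanopyError, FileNotFoundError):
    """A configured input file does not exist."""
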