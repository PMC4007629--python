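"""Exception hierarchy shared across the package."""


class CalcmorphError(Exception):
    """Base class for all calcmorph errors."""


class DataError(CalcmorphError):
    """Malformed or inconsistent input data (files, tables, specs)."""


class GeometryError(CalcmorphError):
    """Degenerate or infeasible geometric configuration."""


class InfeasibleParameterError(GeometryError):
    """A parameter vector cannot be realized as a landmark configuration."""


class MissingLandmarkError(DataError):
    """A landmark file parses but lacks one of the required points A-F."""


class BoundaryError(CalcmorphError):
    """A facet boundary cannot be snapped/closed on the mesh, or leaks."""


class SegmentationError(CalcmorphError):
    """Invalid segmentation request (bad seed, empty label, ...)."""
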