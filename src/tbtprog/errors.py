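"""Exception hierarchy shared across the pipeline stages."""


class TbtError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TbtError, ValueError):
    """A parameter is outside its documented domain."""


class SizeError(ParameterError):
    """A grid or block is too small for the requested operation."""


class GeometryError(TbtError, ValueError):
    """Invalid or degenerate geometry (coincident points, bad layout...)."""


class DegenerateGeometryError(GeometryError):
    """The two extremity landmarks coincide; no baseline can be fitted."""


class IndexConventionError(GeometryError):
    """Landmark indices queried against the wrong laterality convention."""


class OutOfBoundsError(GeometryError):
    """An ROI sampling grid falls outside the image."""


class InsufficientScaleError(TbtError, ValueError):
    """Fewer than two variogram lags fall inside the requested scale band."""


class DegenerateTextureError(TbtError, ValueError):
    """A variogram value is zero inside the fitting band (flat texture)."""


class MissingDataError(TbtError, ValueError):
    """A required clinical field is absent."""


class SchemaError(TbtError, ValueError):
    """Tables do not share the columns a protocol requires."""


class SelectionError(TbtError, RuntimeError):
    """Backward model selection failed (e.g. non-convergent full fit)."""


class UndefinedMetricError(TbtError, ValueError):
    """A metric needs both outcome classes and got only one."""
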