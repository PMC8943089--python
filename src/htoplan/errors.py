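"""Exception hierarchy.

All package-specific failures derive from :class:`HtoError` so callers (and
the CLI) can distinguish handled domain errors from programming errors.
"""


class HtoError(Exception):
    """Base class for all htoplan errors."""


class InvalidLandmarksError(HtoError):
    """A landmark set is incomplete or geometrically degenerate."""


class DegenerateGeometryError(HtoError):
    """A construction (e.g. a line-line intersection) has no solution."""


class PlanningInfeasibleError(HtoError):
    """No rotation below the model limit reaches the correction target."""


class OutOfModelError(HtoError):
    """Inputs are outside the validity range of the gap model."""


class GeometryInconsistentError(HtoError):
    """Measured triangle quantities contradict each other."""


class InconsistentRowError(HtoError):
    """A printed gap pair cannot arise from the model for any cortex angle."""


class FitDegenerateError(HtoError):
    """The wedge fit has no unique solution (collinear measurement points)."""


class DegenerateRegressionError(HtoError):
    """Regression predictor is constant."""


class UndefinedTestError(HtoError):
    """A contingency table has a zero margin."""


class ConfigError(HtoError):
    """Invalid configuration / parameter values."""


class DataError(HtoError):
    """Malformed input data (NaNs, bad lengths, unreadable values)."""


class SchemaError(DataError):
    """A file does not conform to the documented schema."""
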