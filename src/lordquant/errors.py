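"""Typed exceptions raised across the pipeline.

All validation failures derive from :class:`ValidationError` so callers
(and the CLI) can distinguish bad inputs (exit code 2) from estimation
failures (exit code 3).
"""


class LordquantError(Exception):
    """Base class for all package errors."""


class ValidationError(LordquantError):
    """Invalid input data or configuration."""


class ShapeMismatchError(ValidationError):
    """Rasters belonging to one exam do not share a shape."""


class SidecarError(ValidationError):
    """Exam sidecar metadata missing keys or holding invalid values."""


class InvalidConfigError(ValidationError):
    """Cohort or pipeline configuration violates its invariants."""


class DegenerateAnatomyError(ValidationError):
    """Fovea/optic-nerve-head geometry does not admit the operation
    (e.g. zero horizontal fovea-disc separation for the shear)."""


class ResolutionError(ValidationError):
    """Fovea-disc distance too small (in pixels) to build the grid."""


class InsufficientPointsError(ValidationError):
    """Fewer control points than the configured minimum."""


class DegenerateControlPointsError(ValidationError):
    """Control points duplicated or collinear; homography rank-deficient."""


class CapacityError(ValidationError):
    """Requested synthetic atrophy area exceeds what the raster can hold."""


class EstimationError(LordquantError):
    """A statistical fit could not be performed."""


class UnderdeterminedError(EstimationError):
    """Too few distinct ages (or observations) to identify the model."""
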