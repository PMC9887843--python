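"""Exception hierarchy for the NDVI pipeline.

Every stage failure maps to a distinct subclass so that the pipeline
driver can abort with a message naming the offending stage.
"""


class NDVICamError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NDVICamError, ValueError):
    """An input value violates an operation's precondition."""


class BoundsError(NDVICamError, ValueError):
    """A region of interest falls outside the image."""


class SaturatedPatchError(NDVICamError):
    """More than half of a reference patch is saturated."""


class SingularFitError(NDVICamError):
    """Calibration fit is degenerate (e.g. all digital numbers equal)."""


class ConvergenceError(NDVICamError):
    """Iterative calibration fit failed to converge."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class AllSaturatedError(NDVICamError):
    """No exposure in the series keeps the brightest reference below the cap."""


class DegenerateSignalError(NDVICamError):
    """Spectral leak estimate has zero total in-band signal."""


class NoFeaturesError(NDVICamError):
    """An image has zero variance; translation cannot be estimated."""


class DimensionError(NDVICamError, ValueError):
    """Two images that must share a shape do not."""


class UndefinedPixelError(NDVICamError):
    """NDVI is undefined because nir + red is (numerically) zero."""


class EmptyRegionError(NDVICamError):
    """A statistics region contains no valid pixels."""


class FormatError(NDVICamError):
    """Unsupported or lossy image file format."""


class MetadataError(NDVICamError):
    """A 16-bit image is missing or has an inconsistent JSON sidecar."""


class ConfigError(NDVICamError):
    """Run configuration is invalid."""


class SceneSpecError(NDVICamError):
    """Synthetic scene specification is invalid (e.g. overlapping regions)."""


class PipelineStageError(NDVICamError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
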