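"""Exception and warning types shared across the pipeline stages."""


class ContraplaneError(Exception):
    """Base class for all package-specific errors."""


class ObliqueAffineError(ContraplaneError):
    """A NIfTI affine is not axis-aligned; only axis-aligned grids are supported."""


class DegenerateFrameError(ContraplaneError):
    """Raw plane normals are too close to parallel to assemble a frame."""


class InsufficientForegroundError(ContraplaneError):
    """Too few supra-threshold voxels to run clustering or PCA."""


class MissingClassError(ContraplaneError):
    """A required segmentation class is absent from a label volume."""

    def __init__(self, class_name: str):
        self.class_name = class_name
        super().__init__(f"segmentation class '{class_name}' is absent or below the voxel minimum")


class PatchSizeError(ContraplaneError):
    """Requested patch or crop does not fit the volume."""


class PlacementError(ContraplaneError):
    """Phantom placement could not satisfy margin constraints."""


class LateralityError(ContraplaneError):
    """Comparison requires exactly one left and one right frame."""


class PipelineStageError(ContraplaneError):
    """Wraps an error from a pipeline stage with a stage tag."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")


class ConstantVolumeWarning(UserWarning):
    """Normalization of a constant volume: output set to zero."""


class EigenvalueDegeneracyWarning(UserWarning):
    """The PCA eigengap separating in-plane from normal directions is small."""


class DuplicateDetectionWarning(UserWarning):
    """Two k-means centers were merged because they were implausibly close."""


class NonConvergenceWarning(UserWarning):
    """Iterative procedure hit its iteration cap before converging."""
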