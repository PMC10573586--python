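"""Exception hierarchy shared across the package."""


class ChiasmNetError(Exception):
    """Base class for all package errors."""


class ValidationError(ChiasmNetError):
    """Invalid values in user-supplied data (manifests, labels, scores)."""


class ShapeError(ValidationError):
    """Array shape does not match the expected patch/mask geometry."""


class ConfigError(ChiasmNetError):
    """Invalid or inconsistent configuration."""


class InvalidEffectError(ConfigError):
    """Phantom effect configuration produces non-physical parameters."""


class RenderClippedError(ChiasmNetError):
    """Rendered structure is clipped by a patch boundary after jitter."""

    def __init__(self, face: str):
        self.face = face
        super().__init__(f"rendered structure touches patch face: {face}")


class PlacementError(ChiasmNetError):
    """Patch does not fit inside the target volume at the requested center."""


class OutOfBoundsError(ChiasmNetError):
    """Requested center lies outside the volume."""


class CoverageError(ChiasmNetError):
    """Extraction window has too much zero padding."""


class FormatError(ChiasmNetError):
    """File is not a readable NIfTI-1 volume."""


class SplitError(ChiasmNetError):
    """Fold-split composition is infeasible for the cohort."""


class UpsamplingError(ChiasmNetError):
    """Class upsampling requested on degenerate input."""


class DataError(ChiasmNetError):
    """Empty or otherwise unusable training data."""


class MonitoringError(ChiasmNetError):
    """Dev set unusable for training monitoring (e.g. single class)."""


class UndefinedMetricError(ChiasmNetError):
    """Metric is undefined for the given inputs (e.g. single-class AUROC)."""
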