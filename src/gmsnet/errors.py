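"""Exception types shared across the package."""


class GmsnetError(Exception):
    """Base class for all package-specific errors."""


class SizingError(GmsnetError):
    """Volume grid too small for the requested parcellation."""


class GridMismatchError(GmsnetError):
    """Two spatial objects do not share the same voxel grid."""


class EmptyCubeSetError(GmsnetError):
    """No cube passed the gray-matter inclusion criterion."""


class DegenerateCubesError(GmsnetError):
    """All sampled cubes have zero variance; no null distribution exists."""


class NoValidThresholdError(GmsnetError):
    """No correlation threshold achieves the requested spurious-edge rate."""


class CollinearityError(GmsnetError):
    """Covariate design matrix is rank deficient."""


class MissingStageError(GmsnetError):
    """A pipeline stage was requested before its upstream stage ran."""
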