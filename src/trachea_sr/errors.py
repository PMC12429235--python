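"""Exception hierarchy for the trachea surface-roughness pipeline.

Every stage raises a subclass of :class:`TracheaSRError` so batch drivers can
catch one type, record the failure, and move on to the next case.
"""


class TracheaSRError(Exception):
    """Base class for all pipeline errors."""


class MaskIOError(TracheaSRError):
    """File could not be read or written."""


class DimensionalityError(MaskIOError):
    """Image on disk is not a 3D volume."""


class MetadataError(MaskIOError):
    """Voxel spacing missing, zero, or non-finite."""


class ResolutionError(TracheaSRError):
    """Voxel spacing too coarse to resolve the requested geometry."""


class CarinaNotFoundError(TracheaSRError):
    """No persistent airway split found; mask may be trachea-only."""


class SegmentTooShortError(TracheaSRError):
    """Trachea segment shorter than the minimum analyzable length."""


class DegenerateSliceError(TracheaSRError):
    """A slice could not be radially sampled (too many failed rays)."""


class InsufficientScalesError(TracheaSRError):
    """Fewer than four usable box sizes for the log-log fit."""


class WindowError(TracheaSRError):
    """Empty or invalid slice window for the tracheal index."""


class DegenerateInputError(TracheaSRError):
    """Input is structurally valid but empty (e.g. lung mask with no voxels)."""
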