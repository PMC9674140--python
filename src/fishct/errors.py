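"""Exception hierarchy for the fishct pipeline.

Every error raised by the package derives from :class:`FishCTError` so
callers (and the CLI) can catch pipeline failures without masking
programming errors.
"""


class FishCTError(Exception):
    """Base class for all fishct errors."""


class InvalidSpecError(FishCTError, ValueError):
    """A phantom or cohort specification violates its invariants."""


class MetadataError(FishCTError):
    """Required image metadata (e.g. voxel size) is missing."""


class FormatError(FishCTError):
    """A volume file or series is malformed (e.g. missing DICOM slice)."""


class DegenerateHistogramError(FishCTError, ValueError):
    """A histogram has fewer than two nonzero bins; no threshold exists."""


class EmptyBodyError(FishCTError):
    """No voxel exceeds the lower threshold; there is no body to mask."""


class BoundaryUndetectableError(FishCTError):
    """Fewer than two internal air cavities; the swim-bladder boundary
    cannot be located automatically."""


class FusionError(FishCTError):
    """A bone connected component spans more than one expected vertebra."""

    def __init__(self, message, component_ids=None):
        super().__init__(message)
        self.component_ids = tuple(component_ids or ())


class PartitionError(FishCTError):
    """A vertebra cannot be partitioned into its skeletal elements."""


class GeometryError(FishCTError):
    """Arch geometry (length/angle) cannot be measured."""


class DegenerateControlError(FishCTError, ValueError):
    """Control cohort has zero variance (or too few fish) for a z-score."""
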