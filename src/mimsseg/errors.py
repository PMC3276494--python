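"""Exception hierarchy for mimsseg.

All package-specific errors derive from :class:`MimssegError` so callers
can catch everything the library raises with a single clause; each concrete
class also subclasses the closest builtin (ValueError, RuntimeError, ...)
to remain idiomatic.
"""


class MimssegError(Exception):
    """Base class for all mimsseg errors."""


class ValidationError(MimssegError, ValueError):
    """Input data violates a domain-type invariant (negative counts, ...)."""


class ShapeError(MimssegError, ValueError):
    """Array shapes are inconsistent."""


class OverlapError(ValidationError):
    """Two ROIs claim the same pixel."""

    def __init__(self, roi_a: int, roi_b: int):
        self.roi_a = roi_a
        self.roi_b = roi_b
        super().__init__(f"ROIs {roi_a} and {roi_b} overlap: a pixel can "
                         "never be assigned to more than one ROI")


class SamplingError(MimssegError, ValueError):
    """A train/test split cannot be formed (class too small, ...)."""


class StratificationError(MimssegError, ValueError):
    """A class has fewer members than cross-validation folds."""


class PlacementError(MimssegError, RuntimeError):
    """A random ROI translation found no feasible placement."""


class ModelFormatError(MimssegError, ValueError):
    """A model file is truncated, corrupt, or of an unknown version."""


class ScalingStateError(MimssegError, RuntimeError):
    """Feature scaling was applied before being fitted."""
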