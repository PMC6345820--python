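"""Exception hierarchy shared by all pipelines."""


class ClearQuantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ClearQuantError, ValueError):
    """A parameter violates its documented range or type."""


class DegenerateInputError(ClearQuantError, ValueError):
    """Input carries no usable signal (e.g. constant image for Otsu)."""


class NoObjectError(ClearQuantError, ValueError):
    """An operation requiring at least one object received none."""


class CalibrationError(ClearQuantError, RuntimeError):
    """The ruler region yielded no usable scale object."""


class SegmentationError(ClearQuantError, RuntimeError):
    """Segmentation produced an empty result where an object was required."""


class PlacementError(ClearQuantError, RuntimeError):
    """Synthetic scene could not be packed within the attempt budget."""


class StackReadError(ClearQuantError, IOError):
    """A stack file could not be read or lacks required metadata."""
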