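"""Exception hierarchy.

All package-specific failures derive from :class:`FeedcubeError` so callers
can catch one base class at pipeline boundaries.
"""


class FeedcubeError(Exception):
    """Base class for all feedcube errors."""


class DomainError(FeedcubeError, ValueError):
    """An argument violates a mathematical precondition (e.g. negative mass)."""


class DesignError(FeedcubeError, ValueError):
    """A sample-design configuration produces an impossible record."""


class FormatError(FeedcubeError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DimensionError(FeedcubeError, ValueError):
    """Array shapes do not conform."""


class DegenerateSpectrumError(FeedcubeError, ValueError):
    """A spectrum is constant or has a zero normalisation denominator."""


class DegenerateImageError(FeedcubeError, ValueError):
    """An image is constant where contrast is required."""


class EmptySampleError(FeedcubeError, ValueError):
    """A mask selects no foreground pixels."""


class ScatterCorrectionError(FeedcubeError, ValueError):
    """MSC slope is numerically zero for a row."""


class ConvergenceError(FeedcubeError, RuntimeError):
    """A NIPALS component failed to converge within the iteration cap."""


class SplitError(FeedcubeError, ValueError):
    """A calibration/validation split would leave one side empty."""


class DecisionError(FeedcubeError, ValueError):
    """A decision was requested on an empty map."""


class ModelCompatibilityError(FeedcubeError, ValueError):
    """A model cannot be applied to a cube (grid or band mismatch)."""


class ParameterError(FeedcubeError, ValueError):
    """Invalid transform parameters (e.g. even Savitzky-Golay window)."""
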