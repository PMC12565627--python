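"""Exception hierarchy for the senoscope pipeline.

Every stage raises a subclass of :class:`SenoscopeError` so that the
orchestrator can attach stage/input identity when propagating.
"""


class SenoscopeError(Exception):
    """Base class for all senoscope errors."""


class ImageIOError(SenoscopeError):
    """File could not be read or parsed as an image."""


class DimensionalityError(SenoscopeError):
    """Array dimensionality outside the supported 2-D..4-D range."""


class MetadataError(SenoscopeError):
    """Required physical metadata (pixel size) missing or invalid."""


class EmptyMaskError(SenoscopeError):
    """A cell mask with no in-cell pixels."""


class ShapeMismatchError(SenoscopeError):
    """Image and mask shapes disagree."""


class MaskOverlapError(SenoscopeError):
    """Nuclear and cytoplasmic masks overlap."""


class UndefinedRatioError(SenoscopeError):
    """Ratio with a zero denominator (e.g. zero cytoplasmic mean)."""


class DegenerateInputError(SenoscopeError):
    """Input carries no usable signal (e.g. no positive intensities)."""


class SampleSizeError(SenoscopeError):
    """Too few observations for the requested statistic."""


class EstimabilityError(SenoscopeError):
    """Model design is singular; carries the offending term when known."""


class OrderingError(SenoscopeError):
    """Thresholds supplied out of order."""


class DomainError(SenoscopeError):
    """Value outside its mathematical domain (e.g. p-value not in [0, 1])."""


class ScenarioError(SenoscopeError):
    """Invalid synthetic-scenario specification."""


class CapacityError(SenoscopeError):
    """Synthetic cell placement could not satisfy the requested density."""


class ConfigError(SenoscopeError):
    """Run configuration invalid or unresolvable before computation."""
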