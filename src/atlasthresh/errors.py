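"""Exception hierarchy for atlasthresh."""


class AtlasThreshError(Exception):
    """Base class for all atlasthresh errors."""


class ValidationError(AtlasThreshError, ValueError):
    """Invalid configuration, specification or input table."""


class GridCapacityError(ValidationError):
    """More blocks requested than the grid can hold."""


class DegenerateResponseError(AtlasThreshError):
    """The binary response is constant, so no finite logistic MLE exists."""


class InvalidInitializerError(ValidationError):
    """Breakpoint initializer lies outside the observed covariate range."""


class UndefinedAUCError(AtlasThreshError):
    """AUC requested for a single-class response."""


class UndefinedCorrelationError(AtlasThreshError):
    """Rank correlation requested for a constant covariate."""


class NoModelError(AtlasThreshError):
    """Model comparison requested but neither candidate fit exists."""


class BoundsError(ValidationError, IndexError):
    """Raster footprint extends outside the grid."""
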