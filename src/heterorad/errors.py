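"""Exception hierarchy for the heterorad pipeline."""


class HeteroradError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(HeteroradError):
    """Image on disk is not a 3D scalar volume."""


class AlignmentError(HeteroradError):
    """Mask and volume grids do not match."""


class EmptyRoiError(HeteroradError):
    """ROI mask contains no foreground voxels."""


class DegenerateRangeError(HeteroradError):
    """Constant ROI cannot define a quantization range; pass hu_range."""


class InvalidCompositionError(HeteroradError):
    """Subtype percentages are absent, negative, or sum to zero."""


class ConfigurationError(HeteroradError):
    """A required configuration entry (e.g. subtype weight) is missing."""


class UndefinedCorrelationError(HeteroradError):
    """Correlation undefined because an input vector is constant."""


class InsufficientDataError(HeteroradError):
    """Too few complete observations for the requested fit."""


class FoldError(HeteroradError):
    """Cross-validation fold count exceeds the sample size."""


class FeatureSetMissingError(HeteroradError):
    """No direction produced a valid co-occurrence matrix."""


class PhantomSizeError(HeteroradError):
    """Phantom mask too small to host the requested compartments."""


class GroupDefinitionError(HeteroradError):
    """A subtype-count group required by the comparison is empty."""


class RunError(HeteroradError):
    """Every row of a batch run failed."""
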