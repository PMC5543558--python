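"""Exception hierarchy for margin derivation failures."""


class MarginDerivationError(Exception):
    """Base class for all package-specific errors."""


class UnmappableContourError(MarginDerivationError):
    """A planar contour lies farther than half a slice spacing from every grid slice."""


class ProtocolMixingError(MarginDerivationError):
    """Fraction structures registered under different match protocols were combined."""


class GridMismatchError(MarginDerivationError):
    """Two masks that must share a voxel grid do not."""


class EmptyCompositeError(MarginDerivationError):
    """Overlap requested against a composite with zero volume (undefined denominator)."""


class NonConvergenceError(MarginDerivationError):
    """The overlap threshold was not reached within the margin sweep cap."""


class AggregationError(MarginDerivationError):
    """Per-patient records with mixed structure labels or protocols were aggregated."""


class DegenerateSampleError(MarginDerivationError):
    """A statistical test was given a sample it cannot operate on (e.g. zero variance)."""


class UnsupportedOrientationError(MarginDerivationError):
    """A mask volume has a non-axis-aligned affine; resampling is refused."""


class ManifestError(MarginDerivationError):
    """A cohort manifest failed validation."""
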