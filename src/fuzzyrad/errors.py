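"""Typed exceptions shared across the package."""


class FuzzyRadError(Exception):
    """Base class for all package errors."""


class LoadError(FuzzyRadError):
    """Raised when a volume or mask cannot be loaded or fails validation."""


class GridError(FuzzyRadError):
    """Raised when two lattices that must be congruent are not."""


class NormalizationError(FuzzyRadError):
    """Raised when TBR normalization is impossible (empty or non-positive background)."""


class DegenerateSpecError(FuzzyRadError):
    """Raised when a phantom specification cannot produce a valid lesion."""


class MaskError(FuzzyRadError):
    """Raised on invalid mask input (non-binary where binary is required, empty, ...)."""


class DiscretizationError(FuzzyRadError):
    """Raised when no voxel survives the membership threshold."""


class HarmonizationError(FuzzyRadError):
    """Raised when cross-delineation harmonization empties the tables."""


class FoldError(FuzzyRadError):
    """Raised when a valid Monte-Carlo fold configuration cannot be built."""
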