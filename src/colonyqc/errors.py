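"""Labeled error types raised across the pipeline."""


class ColonyQCError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(ColonyQCError, ValueError):
    """A spec object (kernel, k-NN, synthetic image, run config) is malformed."""


class ImageError(ColonyQCError, ValueError):
    """An image could not be loaded or is unusable."""


class NoKeypointsError(ColonyQCError, ValueError):
    """SIFT found no keypoints, so no mean descriptor exists for the image."""


class DimensionMismatchError(ColonyQCError, ValueError):
    """Feature dimensions of two objects do not agree."""


class DegenerateDataError(ColonyQCError, ValueError):
    """Training data cannot support the requested fit (single class,
    degenerate class size, zero-variance vector for a correlation-type
    distance, ...)."""


class SingularSystemError(ColonyQCError, ValueError):
    """A linear system (LS-SVM dual, covariance inverse) is numerically
    singular."""
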