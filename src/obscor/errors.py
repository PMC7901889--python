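"""Exception hierarchy used across the package."""


class ObscorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ObscorError):
    """Malformed on-disk artifact (bad cell, ragged rows, duplicate ids...)."""


class InsufficientDataError(ObscorError):
    """Subject cannot supply the minimum analyzable duration (160 s)."""


class SequenceTooShortError(ObscorError):
    """Series shorter than the largest probed window (N*T < M*w0)."""


class DomainError(ObscorError):
    """Argument outside the mathematical domain of an operation."""


class GeometryError(ObscorError):
    """Node placement could not satisfy the spacing constraints."""


class GenerationError(ObscorError):
    """Synthetic cohort construction failed (e.g. correlation repair)."""


class FitFailureError(ObscorError):
    """Piecewise fit produced unusable breakpoints or degenerate lines."""


class DegenerateFitError(FitFailureError):
    """Too few / collinear points for a line fit."""


class EmptyDistributionError(ObscorError):
    """Histogram requested over an empty link set."""


class ConfigurationError(ObscorError):
    """Pipeline configuration incomplete or inconsistent."""
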