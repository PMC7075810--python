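"""Exception hierarchy shared across the package."""


class AgeGuessError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AgeGuessError):
    """A file does not conform to the expected tabular layout."""


class RangeError(AgeGuessError):
    """A beta value falls outside the closed unit interval."""


class ValidationError(AgeGuessError):
    """A record violates a domain invariant (e.g. non-positive age)."""


class AlignmentError(AgeGuessError):
    """Matrix and metadata share no sample identifiers."""


class AnnotationError(AgeGuessError):
    """A probe lacks the annotation required by the current policy."""


class FitError(AgeGuessError):
    """A regression model could not be fitted on the given data."""


class ShapeError(AgeGuessError):
    """Input dimensions or feature ordering do not match expectations."""


class PipelineError(AgeGuessError):
    """A multi-step workflow reached a degenerate state (e.g. no features)."""


class UndefinedMetricError(AgeGuessError):
    """A metric is mathematically undefined for the given inputs."""
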