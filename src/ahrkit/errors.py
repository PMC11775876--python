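"""Exception hierarchy used across the pipeline."""


class AhrkitError(Exception):
    """Base class for all package errors."""


class FormatError(AhrkitError):
    """A file does not conform to the expected CSV layout."""


class DataError(AhrkitError):
    """File parsed, but the data violate a precondition (e.g. non-monotone time)."""


class ScheduleError(AhrkitError):
    """Protocol schedule is inconsistent (overlapping or unordered events)."""


class TooShortError(AhrkitError):
    """Recording too short for the requested operation."""


class ShapeError(AhrkitError):
    """Array has the wrong number of samples/axes."""


class DegenerateTrainingError(AhrkitError):
    """Training data cannot support the requested model (e.g. one class only)."""


class InsufficientCohortError(AhrkitError):
    """Too few subjects for the requested cross-validation scheme."""


class ConfigurationError(AhrkitError):
    """Invalid run configuration or empty tuning split."""


class AlignmentError(AhrkitError):
    """Two per-window series do not share the same index."""


class UndefinedMetricError(AhrkitError):
    """Metric undefined for the given sample size (n <= p + 1)."""
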