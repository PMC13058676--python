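"""Exception types raised across the package."""


class DrscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DrscreenError):
    """Invalid configuration (probabilities out of range, bad cutpoints, ...)."""


class EmptyCohortError(DrscreenError):
    """An operation that needs at least one patient received none."""


class UngradedPatientError(DrscreenError):
    """Patient has no eye with a gold-standard grade."""


class NoScoreError(DrscreenError):
    """Patient has no eye with a severity score."""


class DegenerateLabelsError(DrscreenError):
    """ROC/Youden input contains only one class."""


class MissingStageError(DrscreenError):
    """A requested stage boundary has no patients on one side."""


class CrossingThresholdsError(DrscreenError):
    """Per-stage Youden cutpoints are not strictly increasing."""


class InconsistentAggregatesError(DrscreenError):
    """Printed aggregate proportions cannot be reconciled with the class totals."""


class UndefinedMetricError(DrscreenError):
    """A sensitivity/specificity denominator is zero."""
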