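"""Typed exceptions raised across the pipeline.

Every error a caller may want to catch selectively gets its own class; all
inherit from :class:`PepXaiError` so blanket handling stays possible.
"""


class PepXaiError(Exception):
    """Base class for all pepxai errors."""


class UnequalLengthError(PepXaiError):
    """Rows of a dataset file do not all have the same series length."""


class ParseError(PepXaiError):
    """A cell that should hold a number could not be parsed."""


class EmptyInputError(PepXaiError):
    """A dataset file or dataset object contains no instances."""


class AlignmentError(PepXaiError):
    """Predictions and dataset rows cannot be aligned."""


class SeriesTooShortError(PepXaiError):
    """A series is too short for run-event extraction (length < 2)."""


class UndefinedSilhouetteError(PepXaiError):
    """Silhouette score requested for a partition with fewer than 2 clusters."""


class NoClustersError(PepXaiError):
    """Event assignment requested against a cluster model with k == 0."""


class ConfigError(PepXaiError):
    """A configuration value is inconsistent or out of range."""


class SchemaError(PepXaiError):
    """A feature table lacks columns the surrogate tree requires."""


class EmptyEvaluationError(PepXaiError):
    """A rate metric was requested over zero instances."""


class RobustnessUndefinedError(PepXaiError):
    """No instance admitted a label-preserving perturbation."""
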