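"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PlasmirError`, so callers (and the
CLI) can distinguish input-validation failures from statistical-stage
failures without string matching.
"""


class PlasmirError(Exception):
    """Base class for all package errors."""


class FormatError(PlasmirError):
    """Malformed input table: duplicate identifiers, unparsable cells."""


class ValidationError(PlasmirError):
    """Sample annotation violates the clinical-table contract."""


class AlignmentError(PlasmirError):
    """Ct matrix and sample table share no sample identifiers."""


class EmptyMatrixError(PlasmirError):
    """A filtering step removed every assay."""


class NormalizationError(PlasmirError):
    """Reference assay unusable (e.g. undetected well) during dCt."""


class NeutralityError(PlasmirError):
    """A group needed for reference-neutrality testing is missing."""


class SelectionError(PlasmirError):
    """No shortlisted assay satisfies the reference criteria."""


class ComparisonError(PlasmirError):
    """A group comparison has too few samples on one side."""


class ScalingError(PlasmirError):
    """Row z-scoring hit a zero-variance assay."""


class SeparationError(PlasmirError):
    """Logistic fit encountered (quasi-)perfect separation."""


class LabelError(PlasmirError):
    """Binary outcome is degenerate (one class absent)."""


class SearchError(PlasmirError):
    """Every candidate model in a marker search failed to fit."""


class DataError(PlasmirError):
    """Empty or invalid data passed to a survival estimator."""


class GroupError(PlasmirError):
    """Two-group survival comparison did not receive two nonempty groups."""


class DesignError(PlasmirError):
    """Every patient was dropped while building a regression design."""


class FitError(PlasmirError):
    """A regression fit failed to converge (e.g. monotone likelihood)."""


class ConfigError(PlasmirError):
    """Invalid simulation or run configuration."""
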