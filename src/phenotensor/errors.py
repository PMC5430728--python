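"""Exception hierarchy for the phenotyping pipeline."""


class PhenotensorError(Exception):
    """Base class for all package errors."""


class SchemaError(PhenotensorError):
    """Input file violates the documented column/enum schema."""


class LabelingError(PhenotensorError):
    """A patient with events has no outcome label (or vice versa where required)."""


class FormatError(PhenotensorError):
    """A serialized artifact (tensor, similarity matrix, report) is corrupted."""


class ParameterError(PhenotensorError):
    """A configuration or operation parameter is out of its valid range."""


class EmptyResultError(PhenotensorError):
    """A filtering step removed every code/event."""


class DegenerateLabelsError(PhenotensorError):
    """A supervised fit was attempted with a single outcome class."""


class UndefinedSimilarityError(PhenotensorError):
    """Cosine similarity requested for a zero vector."""


class DivergenceError(PhenotensorError):
    """The factorization produced non-finite or absurd fit values."""


class UndefinedFitError(PhenotensorError):
    """Fit statistic requested for an all-zero observed tensor."""
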