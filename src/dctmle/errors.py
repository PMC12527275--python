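"""Exception hierarchy for dctmle.

All errors raised on purpose by this package derive from :class:`DCTMLEError`
so callers (in particular the CLI) can distinguish domain failures from bugs.
"""


class DCTMLEError(Exception):
    """Base class for all dctmle errors."""


class DataError(DCTMLEError):
    """Malformed input data: missing cells, bad columns, wrong domains."""


class ColumnError(DataError):
    """A named column is absent from the input."""


class DegenerateOutcomeError(DataError):
    """The outcome is constant, so min-max scaling is undefined."""


class SampleSizeError(DCTMLEError):
    """The sample is too small for the requested operation."""


class SchemaError(DCTMLEError):
    """Prediction-time covariates do not match the training layout."""


class FluctuationError(DCTMLEError):
    """The offset-logistic fluctuation regression failed to converge."""


class EstimationError(DCTMLEError):
    """An estimation step could not be completed (e.g. a degenerate split)."""
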