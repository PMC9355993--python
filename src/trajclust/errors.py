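"""Exception hierarchy for trajclust.

All errors raised by the package derive from :class:`TrajclustError` so
callers can catch the package's failures with a single ``except`` clause.
"""


class TrajclustError(Exception):
    """Base class for all trajclust errors."""


class SchemaError(TrajclustError):
    """A table or archive does not match the expected schema."""


class ParseError(TrajclustError):
    """A cell in an input table could not be parsed."""


class ParameterError(TrajclustError):
    """Invalid simulation or model parameters."""


class EmptyDatasetError(TrajclustError):
    """A filtering step removed every subject."""


class ArchiveIntegrityError(TrajclustError):
    """A model archive is corrupt, truncated, or of the wrong kind."""


class ConvergenceError(TrajclustError):
    """A likelihood optimisation failed to converge."""


class NumericalError(TrajclustError):
    """A numerical operation produced a non-finite or ill-conditioned result."""


class NegativeDurationError(SchemaError):
    """A scan predates the recorded clinical onset age.

    The trajectory model is defined from onset onward, so such visits are
    rejected at ingest rather than silently clipped.
    """


class PipelineError(TrajclustError):
    """A pipeline stage failed; the message names the stage."""
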