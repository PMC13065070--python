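"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`TimeUseCodaError` so callers (and the
CLI) can distinguish configuration mistakes from data problems and from
genuinely infeasible requests.
"""


class TimeUseCodaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TimeUseCodaError):
    """Invalid configuration: bad parameter values, unknown names, bad bases."""


class DataFormatError(TimeUseCodaError):
    """Malformed input data: bad slot indices, unknown codes, duplicates."""


class PreconditionError(TimeUseCodaError):
    """A documented precondition was violated (e.g. zeros before ILR)."""


class DegenerateInputError(TimeUseCodaError):
    """Input with no usable information (e.g. an all-zero composition)."""


class DomainError(TimeUseCodaError):
    """Value outside the mathematical domain of an operation."""


class ModelError(TimeUseCodaError):
    """Model fitting failure, e.g. a rank-deficient design."""


class InfeasibleReallocationError(TimeUseCodaError):
    """A time reallocation would drive some behaviour set to zero or below."""


class PipelineError(TimeUseCodaError):
    """A pipeline stage failed; the message names the stage."""
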