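"""Exception types shared across the package."""


class GaitprintError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(GaitprintError, ValueError):
    """A configuration object violates its invariants."""


class TooShortError(GaitprintError, ValueError):
    """An input series is too short for the requested operation."""


class DegenerateInputError(GaitprintError, ValueError):
    """Input carries no usable signal (zero variance, non-positive heights, ...)."""


class NoEventsError(GaitprintError, ValueError):
    """No gait events could be detected in a recording."""


class PipelineOrderError(GaitprintError, RuntimeError):
    """An operation was applied to data in the wrong processing stage."""


class SchemaError(GaitprintError, ValueError):
    """Array or table does not match the canonical layout."""


class TrainingDivergedError(GaitprintError, RuntimeError):
    """Network training produced non-finite loss."""


class ContractViolationError(GaitprintError, ValueError):
    """A caller-enforced precondition was violated."""


class DegenerateSubspaceError(GaitprintError, ValueError):
    """Data matrix has insufficient rank for the requested projection."""


class UndefinedOverlapError(GaitprintError, ValueError):
    """Overlap is undefined because the reference volume is empty."""
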