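"""Exception hierarchy for cellmatch."""


class CellMatchError(Exception):
    """Base class for all cellmatch errors."""


class InvalidPatternError(CellMatchError):
    """A cell-type pattern specification is empty or malformed."""


class ConfigurationError(CellMatchError):
    """Parameters are missing, inconsistent, or out of their valid range."""


class SamplingError(CellMatchError):
    """Random sequential deposition failed to satisfy the equal-length
    constraint within the attempt budget."""

    def __init__(self, msg: str, best_residual: float | None = None):
        super().__init__(msg)
        self.best_residual = best_residual


class InvalidIntervalError(CellMatchError):
    """An interval was given with start > end."""


class UndefinedMismatchError(CellMatchError):
    """Mismatch requested for a zero-length cell where the limit is ambiguous."""


class InsufficientDataError(CellMatchError):
    """A trajectory or ensemble is too short for the requested statistic."""


class DegenerateGeometryError(CellMatchError):
    """A cell length is non-positive where a positive length is required."""


class TimestepError(CellMatchError):
    """Explicit-Euler integration became unstable; reduce dt."""
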