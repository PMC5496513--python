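"""Exception hierarchy shared across the package."""


class KelpscapeError(Exception):
    """Base class for all package errors."""


class SchemaError(KelpscapeError):
    """An input table is missing required columns."""


class ValidationError(KelpscapeError):
    """A record violates an invariant (e.g. k > m, negative altitude)."""


class ConfigError(KelpscapeError):
    """A generative or pipeline configuration is invalid."""


class ProjectionError(KelpscapeError):
    """Site extent too large for a local planar projection."""


class CapacityError(KelpscapeError):
    """A transect design cannot be placed on the available track."""

    def __init__(self, message: str, max_feasible: int | None = None):
        super().__init__(message)
        self.max_feasible = max_feasible


class SiteTooSmallError(CapacityError):
    """No gap-free track segment is long enough for a single transect."""


class DegenerateInputError(KelpscapeError):
    """Zero-variance or otherwise degenerate statistical input."""


class EmptyBandError(KelpscapeError):
    """A distance band contains no point pairs."""


class InsufficientDataError(KelpscapeError):
    """Too few records or reportable bins for the requested analysis."""


class FitError(KelpscapeError):
    """GLM fitting failed (non-convergence, separation, rank deficiency)."""


class UndefinedAUCError(KelpscapeError):
    """AUC requested with only one class present."""
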