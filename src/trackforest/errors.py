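"""Exception hierarchy for trackforest.

All errors raised by the package derive from :class:`TrackForestError`,
so callers can catch a single base class at tool boundaries.
"""


class TrackForestError(Exception):
    """Base class for all trackforest errors."""


class FormatError(TrackForestError):
    """A file does not conform to the canonical CSV dialect."""


class OrderingError(TrackForestError):
    """Frames or times are not strictly increasing within a cell track."""


class LineageError(TrackForestError):
    """Parent/child structure is inconsistent (orphans, cycles, bad fates)."""


class DatasetValidationError(TrackForestError):
    """A dataset violates one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} invariant violation(s): {lines}{more}")


class InsufficientCellsError(TrackForestError):
    """Fewer root cells than required for frame selection."""


class EmptySelectionError(TrackForestError):
    """An operation received an empty cohort / selection."""


class DegenerateTrackError(TrackForestError):
    """A track has too few points to smooth (fewer than 2)."""


class RangeError(TrackForestError):
    """A requested time interval falls outside a cell's lifespan."""


class ParameterError(TrackForestError):
    """An argument is outside its admissible range."""


class RankError(TrackForestError):
    """A fit or density estimate received degenerate (rank-deficient) input."""


class UndefinedCorrelationError(TrackForestError):
    """Correlation requested on data with zero variance."""


class FitError(TrackForestError):
    """A nonlinear fit failed to converge; diagnostics attached."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConsistencyError(TrackForestError):
    """Cross-references between results and a dataset do not match."""


class ConfigError(TrackForestError):
    """Invalid simulation or run configuration."""
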