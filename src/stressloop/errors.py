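"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`StressloopError`
so callers can distinguish domain failures from programming errors.
"""


class StressloopError(Exception):
    """Base class for all package-specific errors."""


class DegenerateBaselineError(StressloopError):
    """Baseline sigma is zero/negative/non-finite where standardization is required."""


class InvalidWeightsError(StressloopError):
    """Channel weights are all zero, negative, or misaligned."""


class WindowCoverageError(StressloopError):
    """A pre/post analysis window is not covered by enough samples."""


class CatalogIntegrityError(StressloopError):
    """A stimulus catalog is empty, missing ratings, or missing its derived scale."""


class SpecError(StressloopError):
    """A characteristic specification violates its invariants."""


class ProtocolError(StressloopError):
    """A fitting protocol or session procedure violates its preconditions."""


class FittingError(StressloopError):
    """Rule fitting received no usable observations."""


class RankDeficiencyError(FittingError):
    """Least-squares design matrix is rank deficient (e.g. all x identical)."""


class LogIntegrityError(StressloopError):
    """A signal/marker log row is malformed or references unknown entities."""


class SchemaError(LogIntegrityError):
    """A file is missing or mismatching its schema version header."""


class ControllerError(StressloopError):
    """The control loop was invoked with an unusable model or state."""


class SimulationError(StressloopError):
    """The synthetic subject was driven outside its contract (e.g. non-monotone time)."""


class ConfigError(StressloopError):
    """A session configuration file is invalid or contains unknown keys."""


class ReportError(StressloopError):
    """Evaluation/recovery reporting received mismatched inputs."""
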