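"""Exception hierarchy shared across the pipeline."""


class BmhvFlowError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BmhvFlowError, ValueError):
    """A configuration value is outside its allowed set, or a key is unknown."""


class DomainError(BmhvFlowError, ValueError):
    """An argument violates an operation's mathematical domain."""


class GeometryError(BmhvFlowError):
    """The constructed geometry is invalid (e.g. fully occluded valve)."""


class ResolutionError(GeometryError):
    """The grid is too coarse to represent a geometric feature."""


class SolverError(BmhvFlowError, RuntimeError):
    """Time integration failed (divergence, non-convergence, CFL violation)."""


class UndefinedMetricError(BmhvFlowError, ValueError):
    """A Doppler metric is undefined for the given inputs (e.g. zero flow)."""


class ClassificationError(BmhvFlowError, ValueError):
    """A report is missing a metric required by a diagnostic criterion."""


class DegenerateInputError(BmhvFlowError, ValueError):
    """Statistics requested on a degenerate sample (single class, n < 2)."""
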