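"""Exception hierarchy shared across the package."""


class PortoflowError(Exception):
    """Base class for all portoflow errors."""


class ValidationError(PortoflowError):
    """A value violates a physical or structural constraint (e.g. a
    non-positive vessel dimension)."""


class TopologyError(PortoflowError):
    """The vessel graph is malformed (disconnected, dangling references)."""


class ConfigurationError(PortoflowError):
    """A configuration document is inconsistent (missing measurement,
    wrong number of reference outlets, empty parameter list...)."""


class ParameterError(PortoflowError):
    """A function argument is outside its admissible range."""


class ReconciliationError(PortoflowError):
    """Boundary flows cannot be mass-balanced (e.g. zero total outflow
    against non-zero inflow)."""


class PreconditionError(PortoflowError):
    """An operation was invoked on inputs that skipped a required earlier
    step (e.g. solving with unreconciled boundary conditions)."""


class SolverError(PortoflowError):
    """The network linear system is singular or otherwise unsolvable."""


class UndefinedStatisticError(PortoflowError):
    """A statistic is undefined for the given data (e.g. ICC with zero
    total variance)."""
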