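"""Exception hierarchy shared across the planning pipeline."""


class SparcletError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SparcletError):
    """Invalid planning configuration (unknown scenario, bad key, missing ROI)."""


class GeometryError(SparcletError):
    """Phantom/ROI geometry that cannot be realized (ROI larger than body, ...)."""


class PhysicsModelError(SparcletError):
    """Query outside the beam model's validity (energy off the machine grid, ...)."""


class PlanningError(SparcletError):
    """Plan construction failure (target beyond machine range, all spots removed)."""


class ContractViolation(SparcletError):
    """Caller broke an operation precondition (negative weights, bad lengths)."""


class EvaluationError(SparcletError):
    """Plan evaluation on degenerate input (empty ROI, missing maps)."""


class NumericalError(SparcletError):
    """Non-finite values encountered during optimization."""
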