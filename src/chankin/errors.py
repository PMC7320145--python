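"""Exception hierarchy shared across the package."""


class ChankinError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ChankinError, ValueError):
    """Inputs violate a documented precondition (negative concentration, ...)."""


class UndefinedFractionError(InvalidInputError):
    """A fraction was requested with a zero denominator (no ligand, no product)."""


class InsufficientDataError(InvalidInputError):
    """Too few points for the requested fit or window."""


class CoverageError(InvalidInputError):
    """A blank/baseline trace does not cover the time range of the sample trace."""


class FitFailureError(ChankinError):
    """A nonlinear fit did not converge or the data cannot constrain the model."""


class SimulationError(ChankinError):
    """The ODE/PDE integrator failed or produced an unphysical state."""


class StabilityError(SimulationError):
    """Spatial grid too coarse for the sedimentation field (cell Peclet > 2)."""


class BuoyancyError(InvalidInputError):
    """vbar * rho >= 1: the species does not sediment."""


class NoPlateauWarning(UserWarning):
    """An antibody competition series did not reach a stable plateau."""
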