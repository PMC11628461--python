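"""Exception hierarchy for ventpower.

All errors raised by the library derive from :class:`VentpowerError` so that
callers (and the CLI) can distinguish model errors from programming errors.
"""


class VentpowerError(Exception):
    """Base class for all ventpower errors."""


class InvalidParameterError(VentpowerError, ValueError):
    """A physical parameter violates its domain (e.g. non-positive elastance)."""


class DeadSpaceViolationError(VentpowerError, ValueError):
    """Tidal volume does not exceed the anatomic dead space.

    The alveolar-ventilation constraint rr = V'_alv / (V_T - V_D) diverges as
    V_T approaches V_D: a breath no larger than the dead space exchanges no gas
    at any rate.
    """


class DegenerateExpirationError(VentpowerError, ArithmeticError):
    """Expiratory time is so short relative to tau that intrinsic PEEP diverges.

    Raised instead of returning a non-physical, effectively infinite pressure
    when 1 - exp(-t_ex/tau) underflows.
    """


class ConvergenceError(VentpowerError, RuntimeError):
    """The breath-by-breath simulation failed to reach steady state."""


class NoFeasiblePointError(VentpowerError, ValueError):
    """Every point of an optimization search space is infeasible or degenerate."""


class PrecisionError(VentpowerError, ValueError):
    """A numerical step size is too coarse for the requested strict accuracy."""
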