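"""Exception hierarchy for vokinetics.

All package errors derive from :class:`VokineticsError` so callers can
catch everything from this library with a single ``except`` clause.
"""


class VokineticsError(Exception):
    """Base class for all vokinetics errors."""


class OrderRangeError(VokineticsError, ValueError):
    """An order function evaluated outside the admissible range (0, 1]."""


class GridError(VokineticsError, ValueError):
    """A time grid is empty, too short, or not uniform."""


class ConfigurationError(VokineticsError, ValueError):
    """Inconsistent solver configuration (step, horizon, delay alignment)."""


class DivergenceError(VokineticsError, ArithmeticError):
    """The time-stepper produced a non-finite state."""

    def __init__(self, step: int, t: float):
        self.step = step
        self.t = t
        super().__init__(
            f"non-finite state at step {step} (t = {t:g}); "
            "the integration has diverged"
        )


class IntervalError(VokineticsError, ValueError):
    """An evaluation interval is empty or outside the trajectory horizon."""


class ConditionViolationError(VokineticsError, ValueError):
    """A contraction condition kappa_j < 1 fails, so the Ulam-Hyers
    constant psi_j is undefined."""

    def __init__(self, j: int, kappa: float):
        self.j = j
        self.kappa = kappa
        super().__init__(
            f"stability condition violated for component j={j}: "
            f"kappa_{j} = {kappa:g} >= 1, psi_{j} is undefined"
        )
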