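"""Lipschitz, uniqueness and Ulam-Hyers stability certificates.

Under sup-norm trajectory bounds ||S|| <= b1, ||E|| <= b2, ||H|| <= b3,
||P|| <= b4, the four kinetic kernels are Lipschitz with constants

    Phi1 = beta1*b2,  Phi2 = beta1*b1,  Phi3 = beta3 + beta2,  Phi4 = beta3,

and zeta = max_j Phi_j.  With the kernel mass

    kappa_tilde(t) = t^{delta(t)} / Gamma(delta(t) + 1),

the solution is unique on [0, t] when kappa_j = kappa_tilde * Phi_j <= 1,
and the model is Ulam-Hyers stable with constants

    psi_j = kappa_tilde / (1 - kappa_tilde * Phi_j)     (kappa_j < 1):

any epsilon-approximate solution (a trajectory whose residual against
kernel j is bounded by epsilon_j) stays within psi_j * epsilon_j of the
exact solution in sup norm.

The contraction conditions hold on short horizons (e.g. [0, 1] with the
reference parameterization) and fail for t ~ 200, where the bound is
vacuous; :func:`uh_experiment` therefore refuses intervals on which the
condition fails unless explicitly overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .enzyme import COMPARTMENTS, EnzymeState, KineticParameters, make_enzyme_rhs
from .exceptions import ConditionViolationError, IntervalError
from .fractional import OrderFunction, kappa_tilde
from .solver import (
    DelayedSystemSpec,
    SolverConfig,
    TrajectoryGrid,
    solve_vofdde,
)

__all__ = [
    "TrajectoryBounds",
    "LipschitzConstants",
    "StabilityReport",
    "trajectory_bounds",
    "lipschitz_constants",
    "uniqueness_condition",
    "ulam_hyers_constants",
    "uh_experiment",
    "make_stability_report",
    "UHExperimentResult",
]


@dataclass(frozen=True)
class TrajectoryBounds:
    """Sup-norm bounds b1..b4 on S, E, H, P over a stated interval."""

    b1: float
    b2: float
    b3: float
    b4: float

    def __post_init__(self) -> None:
        if min(self.b1, self.b2, self.b3, self.b4) < 0:
            raise ValueError("bounds must be non-negative")

    def as_tuple(self) -> tuple:
        return (self.b1, self.b2, self.b3, self.b4)


@dataclass(frozen=True)
class LipschitzConstants:
    """Per-kernel Lipschitz constants and their maximum zeta."""

    phi1: float
    phi2: float
    phi3: float
    phi4: float

    @property
    def zeta(self) -> float:
        return max(self.phi1, self.phi2, self.phi3, self.phi4)

    def as_tuple(self) -> tuple:
        return (self.phi1, self.phi2, self.phi3, self.phi4)


def trajectory_bounds(
    traj: TrajectoryGrid,
    interval: tuple[float, float] | None = None,
) -> TrajectoryBounds:
    """Per-compartment max absolute value over ``interval`` (default: all)."""
    if interval is None:
        mask = np.ones(len(traj.t), dtype=bool)
    else:
        a, b = interval
        if b < a:
            raise IntervalError(f"empty interval [{a:g}, {b:g}]")
        if a < traj.t[0] - 1e-12 or b > traj.t[-1] + 1e-12:
            raise IntervalError(
                f"interval [{a:g}, {b:g}] outside trajectory horizon"
            )
        mask = (traj.t >= a - 1e-12) & (traj.t <= b + 1e-12)
        if not mask.any():
            raise IntervalError(f"interval [{a:g}, {b:g}] contains no grid node")
    sup = np.abs(traj.y[mask]).max(axis=0)
    return TrajectoryBounds(*[float(s) for s in sup])


def lipschitz_constants(
    params: KineticParameters,
    bounds: TrajectoryBounds,
) -> LipschitzConstants:
    """Phi1 = beta1*b2, Phi2 = beta1*b1, Phi3 = beta3+beta2, Phi4 = beta3."""
    return LipschitzConstants(
        phi1=params.beta1 * bounds.b2,
        phi2=params.beta1 * bounds.b1,
        phi3=params.beta3 + params.beta2,
        phi4=params.beta3,
    )


def uniqueness_condition(
    t: float,
    order: OrderFunction,
    phi: float,
) -> tuple[float, bool]:
    """Contraction factor kappa = kappa_tilde(t) * Phi and its status.

    The solution is unique on [0, t] when kappa <= 1.
    """
    kappa = kappa_tilde(t, order) * phi
    return kappa, bool(kappa <= 1.0)


def ulam_hyers_constants(
    t: float,
    order: OrderFunction,
    phis: Sequence[float] | LipschitzConstants,
) -> tuple[float, ...]:
    """Ulam-Hyers constants psi_j = kappa_tilde / (1 - kappa_tilde*Phi_j).

    Raises :class:`ConditionViolationError` naming the first component j
    whose contraction factor kappa_j = kappa_tilde * Phi_j is >= 1.
    """
    if isinstance(phis, LipschitzConstants):
        phis = phis.as_tuple()
    kt = kappa_tilde(t, order)
    psis = []
    for j, phi in enumerate(phis, start=1):
        kappa = kt * phi
        if kappa >= 1.0:
            raise ConditionViolationError(j, kappa)
        psis.append(kt / (1.0 - kappa))
    return tuple(psis)


@dataclass(frozen=True)
class StabilityReport:
    """Aggregated stability certificate for one parameterization."""

    interval: tuple
    bounds: TrajectoryBounds
    constants: LipschitzConstants
    kappas: tuple
    uniqueness_satisfied: tuple
    psis: tuple  # per-component psi_j, or None where kappa_j >= 1
    order_formula: str

    def to_dict(self) -> dict:
        return {
            "interval": list(self.interval),
            "order": self.order_formula,
            "bounds": {
                "b1": self.bounds.b1, "b2": self.bounds.b2,
                "b3": self.bounds.b3, "b4": self.bounds.b4,
            },
            "lipschitz": {
                "phi1": self.constants.phi1, "phi2": self.constants.phi2,
                "phi3": self.constants.phi3, "phi4": self.constants.phi4,
                "zeta": self.constants.zeta,
            },
            "uniqueness": {
                f"kappa{j + 1}": {
                    "value": self.kappas[j],
                    "satisfied": bool(self.uniqueness_satisfied[j]),
                }
                for j in range(4)
            },
            "ulam_hyers": {
                f"psi{j + 1}": self.psis[j] for j in range(4)
            },
        }


def make_stability_report(
    params: KineticParameters,
    traj: TrajectoryGrid,
    interval: tuple[float, float],
    order: OrderFunction,
    bounds: TrajectoryBounds | None = None,
) -> StabilityReport:
    """Build the full certificate at t = interval end.

    Bounds default to trajectory-derived sup norms over the interval;
    user-specified bounds are accepted for reproducing hand calculations.
    """
    if bounds is None:
        bounds = trajectory_bounds(traj, interval)
    consts = lipschitz_constants(params, bounds)
    t_end = interval[1]
    kt = kappa_tilde(t_end, order)
    kappas = tuple(kt * phi for phi in consts.as_tuple())
    satisfied = tuple(k <= 1.0 for k in kappas)
    psis = tuple(
        (kt / (1.0 - k)) if k < 1.0 else None for k in kappas
    )
    return StabilityReport(
        interval=tuple(interval), bounds=bounds, constants=consts,
        kappas=kappas, uniqueness_satisfied=satisfied, psis=psis,
        order_formula=order.formula(),
    )


@dataclass(frozen=True)
class UHExperimentResult:
    """Outcome of one empirical Ulam-Hyers perturbation experiment."""

    epsilon: float
    deviations: tuple  # per-compartment sup |y - y_hat|
    bounds: tuple      # per-compartment psi_j * epsilon
    holds: tuple       # per-compartment deviation <= bound
    psis: tuple
    perturbed_components: tuple

    @property
    def all_hold(self) -> bool:
        return all(self.holds)


def _validate_perturbation(theta: Callable[[float], float], epsilon: float,
                           T: float, n_samples: int = 1000) -> None:
    ts = np.linspace(0.0, T, n_samples)
    vals = np.array([theta(t) for t in ts], dtype=float)
    if np.any(np.abs(vals) > epsilon * (1 + 1e-12)):
        worst = ts[int(np.argmax(np.abs(vals)))]
        raise ValueError(
            f"perturbation exceeds epsilon = {epsilon:g} at t = {worst:g} "
            f"(|theta| = {np.max(np.abs(vals)):g}); supply a bounded function"
        )


def uh_experiment(
    params: KineticParameters,
    y0: EnzymeState,
    order: OrderFunction,
    delays: tuple[float, float],
    epsilon: float,
    perturbation: Callable[[float], float],
    config: SolverConfig | None = None,
    components: Sequence[int] = (0,),
    allow_condition_violation: bool = False,
) -> UHExperimentResult:
    """Empirically test the Ulam-Hyers bound by direct perturbation.

    Integrates the enzyme model twice with identical solver settings:
    once unperturbed, once with the bounded residual ``theta(t)``
    (|theta| <= epsilon, checked by dense sampling) added to the selected
    kernel equations.  Returns per-compartment sup deviations, the
    theoretical bounds psi_j * epsilon, and whether each holds.

    The experiment refuses horizons on which any contraction factor
    kappa_j >= 1 (the bound is then vacuous) unless
    ``allow_condition_violation`` downgrades the error to a warning.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if config is None:
        config = SolverConfig(h=0.01, T=1.0)
    T = config.T
    _validate_perturbation(perturbation, epsilon, T)

    base_system = make_enzyme_rhs(params, tau1=delays[0], tau2=delays[1])
    base = solve_vofdde(base_system, y0.as_array(), order, config)

    bounds = trajectory_bounds(base)
    consts = lipschitz_constants(params, bounds)
    kt = kappa_tilde(T, order)
    kappas = [kt * phi for phi in consts.as_tuple()]
    violated = [j + 1 for j, k in enumerate(kappas) if k >= 1.0]
    if violated:
        if not allow_condition_violation:
            raise ConditionViolationError(violated[0], kappas[violated[0] - 1])
        warnings.warn(
            f"contraction condition fails for components {violated} on "
            f"[0, {T:g}]; the Ulam-Hyers bound is vacuous there"
        )
    psis = tuple(
        kt / (1.0 - k) if k < 1.0 else float("inf") for k in kappas
    )

    comp_set = tuple(sorted(set(int(c) for c in components)))
    if any(c not in range(4) for c in comp_set):
        raise ValueError(f"components must be in 0..3, got {components}")
    base_rhs = base_system.rhs

    def perturbed_rhs(t, y, y1, y2):
        f = np.array(base_rhs(t, y, y1, y2), dtype=float)
        th = perturbation(t)
        for c in comp_set:
            f[c] += th
        return f

    pert_system = replace(base_system, rhs=perturbed_rhs)
    pert = solve_vofdde(pert_system, y0.as_array(), order, config)

    devs = tuple(float(d) for d in np.abs(pert.y - base.y).max(axis=0))
    ub = tuple(p * epsilon for p in psis)
    holds = tuple(d <= b * (1 + 1e-9) + 1e-15 for d, b in zip(devs, ub))
    return UHExperimentResult(
        epsilon=epsilon, deviations=devs, bounds=ub, holds=holds,
        psis=psis,
        perturbed_components=tuple(COMPARTMENTS[c] for c in comp_set),
    )
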