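"""Variable fractional order functions and product-integration quadrature.

This module provides the two primitives everything else is built on:

* :class:`OrderFunction` -- a named, evaluable time-dependent fractional
  order delta(t) constrained to (0, 1].  The convention used throughout
  the package is "order frozen at the outer evaluation time": when the
  Riemann-Liouville integral is evaluated at time t, both the kernel
  exponent and the Gamma factor use alpha = delta(t), so

      I^{delta(t)} G(t) = 1/Gamma(delta(t)) * int_0^t (t-v)^{delta(t)-1} G(v) dv.

* Diethelm-type product-integration weights for the weakly singular
  Volterra kernel (t-v)^{alpha-1}/Gamma(alpha): a product-rectangle
  (forward Euler like) predictor rule and a product-trapezoid corrector
  rule.  At alpha = 1 these reduce exactly to the classical rectangle
  and composite trapezoid rules.

Gamma factors are evaluated through ``scipy.special.gammaln`` for
numerical robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .exceptions import GridError, OrderRangeError

__all__ = [
    "OrderFunction",
    "QuadratureWeights",
    "eval_order",
    "make_weights",
    "rl_integral",
    "kappa_tilde",
]

_FAMILIES = ("constant", "cosine", "sine", "linear")


@dataclass(frozen=True)
class OrderFunction:
    """A time-dependent fractional order delta(t) in (0, 1].

    Parameters
    ----------
    family:
        One of ``constant``, ``cosine``, ``sine``, ``linear``.
    base:
        Baseline order level (dimensionless).
    amplitude:
        Oscillation amplitude for the cosine/sine families (dimensionless).
    timescale:
        Oscillation time scale; the argument of cos/sin is ``t / timescale``.
    slope:
        Linear drift rate (per unit time) for the ``linear`` family.
    label:
        Optional display label, e.g. for table column headers.

    The families evaluate as

    ======== ==========================================
    constant ``base``
    cosine   ``base + amplitude * cos(t / timescale)``
    sine     ``base + amplitude * sin(t / timescale)``
    linear   ``base + slope * t``
    ======== ==========================================

    Evaluation outside (0, 1] raises :class:`OrderRangeError`; values are
    never silently clamped.
    """

    family: str
    base: float
    amplitude: float = 0.0
    timescale: float = 1.0
    slope: float = 0.0
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown order-function family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.family in ("cosine", "sine") and self.timescale == 0:
            raise ValueError("timescale must be nonzero for cosine/sine families")

    def __call__(self, t):
        return eval_order(self, t)

    @property
    def is_constant_one(self) -> bool:
        """True when delta(t) is identically 1 (the classical regime)."""
        return self.family == "constant" and self.base == 1.0

    def formula(self) -> str:
        """Human-readable formula, used in logs and output metadata."""
        if self.family == "constant":
            return f"delta(t) = {self.base:g}"
        if self.family == "cosine":
            return (
                f"delta(t) = {self.base:g} + {self.amplitude:g}"
                f"*cos(t/{self.timescale:g})"
            )
        if self.family == "sine":
            return (
                f"delta(t) = {self.base:g} + {self.amplitude:g}"
                f"*sin(t/{self.timescale:g})"
            )
        return f"delta(t) = {self.base:g} + ({self.slope:g})*t"


def eval_order(spec: OrderFunction, t):
    """Evaluate delta(t) and validate that the result lies in (0, 1].

    ``t`` may be a scalar or an array; negative times are rejected.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError(f"order function evaluated at negative time t={t!r}")
    if spec.family == "constant":
        val = np.full_like(tt, spec.base)
    elif spec.family == "cosine":
        val = spec.base + spec.amplitude * np.cos(tt / spec.timescale)
    elif spec.family == "sine":
        val = spec.base + spec.amplitude * np.sin(tt / spec.timescale)
    else:  # linear
        val = spec.base + spec.slope * tt
    bad = (val <= 0.0) | (val > 1.0)
    if np.any(bad):
        t_bad = float(np.atleast_1d(tt)[np.atleast_1d(bad)][0])
        v_bad = float(np.atleast_1d(val)[np.atleast_1d(bad)][0])
        raise OrderRangeError(
            f"order function {spec.formula()} evaluates to {v_bad:g} at "
            f"t = {t_bad:g}, outside the admissible range (0, 1]"
        )
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class QuadratureWeights:
    """Product-integration weights for one step of the Volterra update.

    For step index ``n`` (producing the solution at ``t_{n+1} = (n+1) h``),
    ``predictor`` holds the n+1 product-rectangle weights over nodes
    ``t_0 .. t_n`` and ``corrector`` the n+2 product-trapezoid weights over
    ``t_0 .. t_{n+1}``, both for the kernel (t-v)^{alpha-1}/Gamma(alpha).
    """

    h: float
    n: int
    alpha: float
    predictor: np.ndarray
    corrector: np.ndarray


def _gamma(x: float) -> float:
    return float(np.exp(gammaln(x)))


def make_weights(n: int, h: float, alpha: float) -> QuadratureWeights:
    """Predictor (rectangle) and corrector (trapezoid) weights at step ``n``.

    The corrector weights are ``h^alpha / Gamma(alpha+2) * a_j`` with the
    classical Adams-Bashforth-Moulton coefficients

        a_0     = n^{alpha+1} - (n - alpha) (n+1)^alpha
        a_j     = (n-j+2)^{alpha+1} + (n-j)^{alpha+1} - 2 (n-j+1)^{alpha+1}
        a_{n+1} = 1

    and the predictor weights are
    ``h^alpha / Gamma(alpha+1) * [(n+1-j)^alpha - (n-j)^alpha]``.

    Their total mass is exact: the corrector weights sum to
    ``t_{n+1}^alpha / Gamma(alpha+1)``, the kernel mass over [0, t_{n+1}].
    """
    if n < 0:
        raise ValueError(f"step index n must be >= 0, got {n}")
    if h <= 0:
        raise ValueError(f"step size h must be positive, got {h}")
    if not 0.0 < alpha <= 1.0:
        raise OrderRangeError(f"alpha = {alpha:g} outside (0, 1]")
    j = np.arange(n + 1, dtype=float)
    predictor = h**alpha / _gamma(alpha + 1.0) * (
        (n + 1 - j) ** alpha - (n - j) ** alpha
    )
    a = np.empty(n + 2)
    a[0] = n ** (alpha + 1.0) - (n - alpha) * (n + 1.0) ** alpha
    if n >= 1:
        jj = np.arange(1, n + 1, dtype=float)
        a[1:-1] = (
            (n - jj + 2.0) ** (alpha + 1.0)
            + (n - jj) ** (alpha + 1.0)
            - 2.0 * (n - jj + 1.0) ** (alpha + 1.0)
        )
    a[-1] = 1.0
    corrector = a * h**alpha / _gamma(alpha + 2.0)
    return QuadratureWeights(h=h, n=n, alpha=alpha, predictor=predictor,
                             corrector=corrector)


def corrector_weights(n: int, h: float, alpha: float) -> np.ndarray:
    """Corrector weight row only (used in the solver's hot loop)."""
    a = np.empty(n + 2)
    a[0] = n ** (alpha + 1.0) - (n - alpha) * (n + 1.0) ** alpha
    if n >= 1:
        jj = np.arange(1, n + 1, dtype=float)
        a[1:-1] = (
            (n - jj + 2.0) ** (alpha + 1.0)
            + (n - jj) ** (alpha + 1.0)
            - 2.0 * (n - jj + 1.0) ** (alpha + 1.0)
        )
    a[-1] = 1.0
    return a * h**alpha / _gamma(alpha + 2.0)


def predictor_weights(n: int, h: float, alpha: float) -> np.ndarray:
    """Predictor weight row only (used in the solver's hot loop)."""
    j = np.arange(n + 1, dtype=float)
    return h**alpha / _gamma(alpha + 1.0) * (
        (n + 1 - j) ** alpha - (n - j) ** alpha
    )


def rl_integral(values: np.ndarray, t: np.ndarray, order: OrderFunction) -> np.ndarray:
    """Variable-order Riemann-Liouville integral of sampled values.

    Approximates, at every grid node ``t_n``,

        (1 / Gamma(delta(t_n))) * int_0^{t_n} (t_n - v)^{delta(t_n)-1} G(v) dv

    with the order frozen at the outer time ``t_n``, using the
    product-trapezoid rule over the uniform grid.  The value at ``t_0 = 0``
    is 0 by definition.

    Parameters
    ----------
    values:
        Samples of G on the grid, shape (N+1,) or (N+1, d).
    t:
        The uniform grid, starting at 0.
    order:
        The order function delta(t).
    """
    t = np.asarray(t, dtype=float)
    G = np.asarray(values, dtype=float)
    if t.size == 0 or G.size == 0:
        raise GridError("empty grid")
    if t.size < 2:
        raise GridError("grid must contain at least 2 points")
    if G.shape[0] != t.size:
        raise GridError(
            f"values ({G.shape[0]} rows) do not match grid ({t.size} points)"
        )
    dt = np.diff(t)
    h = dt[0]
    if h <= 0 or not np.allclose(dt, h, rtol=1e-9, atol=1e-12):
        raise GridError("grid is not uniform")
    out = np.zeros_like(G, dtype=float)
    for n in range(1, t.size):
        alpha = eval_order(order, t[n])
        w = corrector_weights(n - 1, h, alpha)  # nodes 0 .. n
        out[n] = w @ G[: n + 1]
    return out


def kappa_tilde(t: float, order: OrderFunction) -> float:
    """The kernel mass t^{delta(t)} / Gamma(delta(t) + 1).

    This factor appears both as the exact RL integral of a unit integrand
    and as the contraction factor in the uniqueness and Ulam-Hyers
    conditions.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t == 0:
        return 0.0
    delta = eval_order(order, t)
    return float(t**delta / np.exp(gammaln(delta + 1.0)))
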