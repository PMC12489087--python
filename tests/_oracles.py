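"""Independent numerical oracles used by the test suite only."""

import numpy as np
from scipy.special import gammaln


def mittag_leffler_half_neg_sqrt(t, terms=80):
    """Truncated series for E_{1/2}(-sqrt(t)) = sum_k (-sqrt(t))^k / Gamma(k/2+1).

    Independent oracle for the scalar problem D^{1/2} y = -y, y(0) = 1,
    whose closed form is e^t erfc(sqrt(t)).
    """
    t = np.asarray(t, dtype=float)
    z = -np.sqrt(t)
    k = np.arange(terms)
    coeff = np.exp(-gammaln(k / 2.0 + 1.0))
    return np.sum(coeff * z[..., None] ** k, axis=-1)


def brute_force_lipschitz(kernel, component, box, n_grid=12, n_pairs=9):
    """Dense-sampling estimate of the Lipschitz constant of a kinetic
    kernel with respect to one state component.

    Samples states on a grid over ``box`` (per-component upper bounds),
    perturbs the chosen component across ``n_pairs`` alternative values,
    and returns the supremum of |L(x) - L(x_hat)| / |x_c - x_hat_c|.
    """
    axes = [np.linspace(0.0, b, n_grid) for b in box]
    grids = np.meshgrid(*axes, indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1)
    alts = np.linspace(0.0, box[component], n_pairs)
    best = 0.0
    for x in states:
        fx = kernel(x)
        for a in alts:
            if a == x[component]:
                continue
            xh = x.copy()
            xh[component] = a
            ratio = abs(kernel(xh) - fx) / abs(a - x[component])
            best = max(best, ratio)
    return best
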