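"""Lipschitz constants, uniqueness factors and Ulam-Hyers certificates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vokinetics import (
    ConditionViolationError,
    IntervalError,
    KineticParameters,
    OrderFunction,
    SolverConfig,
    TrajectoryBounds,
    kappa_tilde,
    lipschitz_constants,
    make_enzyme_rhs,
    make_stability_report,
    trajectory_bounds,
    uh_experiment,
    ulam_hyers_constants,
    uniqueness_condition,
)
from vokinetics.solver import TrajectoryGrid

from _oracles import brute_force_lipschitz

BETA = KineticParameters(0.053, 0.012, 0.040)
ORDER1 = OrderFunction("constant", 1.0)


def constant_traj(values, T=1.0, n=10):
    t = np.linspace(0, T, n + 1)
    y = np.tile(np.asarray(values, dtype=float), (n + 1, 1))
    return TrajectoryGrid(t=t, y=y, order=None,
                          config=SolverConfig(h=T / n, T=T), metadata={})


class TestBounds:
    def test_constant_trajectory(self):
        b = trajectory_bounds(constant_traj([10, 5, 4, 0.1]))
        assert b.as_tuple() == (10, 5, 4, 0.1)

    def test_zero_state(self):
        b = trajectory_bounds(constant_traj([0, 0, 0, 0]))
        assert b.as_tuple() == (0, 0, 0, 0)

    def test_conservation_caps_enzyme_bound(self, rk4_zero_delay):
        """E + H = 9 with both non-negative, so sup E <= 9."""
        b = trajectory_bounds(rk4_zero_delay, (0.0, 200.0))
        assert b.b2 <= 9.0 + 1e-9
        assert b.b1 == pytest.approx(10.0, rel=1e-6)  # S starts at its max

    def test_empty_or_outside_interval_rejected(self, rk4_zero_delay):
        with pytest.raises(IntervalError):
            trajectory_bounds(rk4_zero_delay, (5.0, 1.0))
        with pytest.raises(IntervalError):
            trajectory_bounds(rk4_zero_delay, (0.0, 300.0))


class TestLipschitz:
    def test_reference_hand_calculation(self):
        c = lipschitz_constants(BETA, TrajectoryBounds(10, 9, 9, 1))
        assert c.as_tuple() == pytest.approx((0.477, 0.530, 0.052, 0.040))
        assert c.zeta == pytest.approx(0.530)

    def test_zero_rates(self):
        c = lipschitz_constants(KineticParameters(0, 0, 0),
                                TrajectoryBounds(10, 9, 9, 1))
        assert c.as_tuple() == (0, 0, 0, 0)
        assert c.zeta == 0

    def test_zero_bounds_leave_rate_only_constants(self):
        c = lipschitz_constants(BETA, TrajectoryBounds(0, 0, 0, 0))
        assert c.phi1 == 0 and c.phi2 == 0
        assert c.phi3 == pytest.approx(0.052)
        assert c.phi4 == pytest.approx(0.040)

    def test_matches_brute_force_kernel_sampling(self):
        """The closed-form constants agree with dense finite-difference
        Lipschitz estimates of each kernel over the bounded box."""
        box = (10.0, 9.0, 9.0, 1.0)
        consts = lipschitz_constants(BETA, TrajectoryBounds(*box))
        rhs = make_enzyme_rhs(BETA).rhs

        def kernel(j):
            def L(x):
                return rhs(0.0, x, x, x)[j]
            return L

        # kernel j is Lipschitz in its own compartment: L1 in S, L2 in E,
        # L3 in H, L4 in P
        for j, phi in enumerate(consts.as_tuple()):
            est = brute_force_lipschitz(kernel(j), j, box)
            assert est == pytest.approx(phi, rel=0.05)


class TestUniquenessCondition:
    @pytest.mark.parametrize(
        "t, phi, expected, ok",
        [
            (1.0, 0.53, 0.53, True),
            (0.0, 0.53, 0.0, True),
            (200.0, 0.53, 106.0, False),
        ],
    )
    def test_integer_order_cases(self, t, phi, expected, ok):
        kappa, satisfied = uniqueness_condition(t, ORDER1, phi)
        assert kappa == pytest.approx(expected)
        assert satisfied is ok

    def test_kappa_vanishes_at_zero_for_all_families(self):
        for spec in (ORDER1, OrderFunction("constant", 0.5),
                     OrderFunction("cosine", 0.98, amplitude=0.008,
                                   timescale=10),
                     OrderFunction("linear", 0.99, slope=-1e-4)):
            assert kappa_tilde(0.0, spec) == 0.0


class TestUlamHyersConstants:
    def test_hand_calculations_at_unit_time(self):
        assert ulam_hyers_constants(1.0, ORDER1, [0.5])[0] == \
            pytest.approx(2.0)
        assert ulam_hyers_constants(1.0, ORDER1, [0.477])[0] == \
            pytest.approx(1 / 0.523, abs=1e-5)
        # Phi = 0 reduces psi to the bare kernel mass
        assert ulam_hyers_constants(1.0, ORDER1, [0.0])[0] == \
            pytest.approx(kappa_tilde(1.0, ORDER1))

    def test_condition_violation_names_component(self):
        with pytest.raises(ConditionViolationError, match="j=2"):
            ulam_hyers_constants(200.0, ORDER1, [0.001, 0.53, 0.001, 0.001])

    @settings(deadline=None, max_examples=60)
    @given(
        t=st.floats(min_value=0.01, max_value=1.5),
        phi=st.floats(min_value=0.0, max_value=0.6),
        dphi=st.floats(min_value=1e-6, max_value=0.05),
        dt=st.floats(min_value=1e-4, max_value=0.2),
        base=st.floats(min_value=0.3, max_value=1.0),
    )
    def test_psi_monotone_in_phi_and_time(self, t, phi, dphi, dt, base):
        order = OrderFunction("constant", base)
        if kappa_tilde(t + dt, order) * (phi + dphi) >= 0.999:
            return  # outside the contraction regime
        p0 = ulam_hyers_constants(t, order, [phi])[0]
        assert ulam_hyers_constants(t, order, [phi + dphi])[0] > p0
        assert ulam_hyers_constants(t + dt, order, [phi])[0] > p0

    def test_psi_vanishes_as_t_to_zero(self):
        psis = [ulam_hyers_constants(t, ORDER1, [0.5])[0]
                for t in (1e-2, 1e-4, 1e-6)]
        assert psis[0] > psis[1] > psis[2]
        assert psis[2] < 1e-5


class TestStabilityReport:
    def test_unit_interval_certificate(self, paper_params, paper_y0,
                                       rk4_zero_delay):
        rep = make_stability_report(paper_params, rk4_zero_delay,
                                    (0.0, 1.0), ORDER1)
        assert rep.constants.zeta == pytest.approx(
            max(rep.constants.as_tuple()))
        assert all(rep.uniqueness_satisfied)
        assert all(p is not None and p > 0 for p in rep.psis)

    def test_long_horizon_flags_condition_failure(self, paper_params,
                                                  rk4_zero_delay):
        rep = make_stability_report(paper_params, rk4_zero_delay,
                                    (0.0, 200.0), ORDER1)
        assert not all(rep.uniqueness_satisfied)
        # kappa for Phi2 = beta1*b1 ~ 0.53 exceeds 1 at t=200
        assert rep.kappas[1] > 1
        assert rep.psis[1] is None
        d = rep.to_dict()
        assert d["uniqueness"]["kappa2"]["satisfied"] is False


class TestUHExperiment:
    CFG = SolverConfig(h=0.01, T=1.0)

    def test_zero_perturbation_gives_zero_deviation(self, paper_params,
                                                    paper_y0):
        res = uh_experiment(paper_params, paper_y0, ORDER1, (0, 0),
                            epsilon=0.01, perturbation=lambda t: 0.0,
                            config=self.CFG)
        assert res.deviations == (0.0, 0.0, 0.0, 0.0)
        assert res.all_hold

    def test_constant_perturbation_within_bound(self, paper_params,
                                                paper_y0):
        eps = 0.01
        res = uh_experiment(paper_params, paper_y0, ORDER1, (0, 0),
                            epsilon=eps, perturbation=lambda t: eps,
                            config=self.CFG, components=(0,))
        assert res.deviations[0] > 0
        assert res.deviations[0] <= res.bounds[0]
        assert res.all_hold

    def test_sinusoidal_perturbation_on_substrate(self, paper_params,
                                                  paper_y0):
        eps = 0.01
        res = uh_experiment(paper_params, paper_y0,
                            OrderFunction("constant", 0.97), (0, 0),
                            epsilon=eps,
                            perturbation=lambda t: eps * np.sin(t),
                            config=self.CFG, components=(0,))
        assert res.deviations[0] <= res.psis[0] * eps
        assert res.all_hold

    def test_deviation_scales_linearly_with_epsilon(self, paper_params,
                                                    paper_y0):
        devs = []
        for eps in (0.01, 0.005, 0.0025):
            res = uh_experiment(paper_params, paper_y0, ORDER1, (0, 0),
                                epsilon=eps, perturbation=lambda t: eps,
                                config=self.CFG)
            devs.append(res.deviations[0])
            assert res.deviations[0] / eps <= res.psis[0]
        assert devs[0] / devs[1] == pytest.approx(2.0, rel=0.05)
        assert devs[1] / devs[2] == pytest.approx(2.0, rel=0.05)

    def test_unbounded_perturbation_rejected(self, paper_params, paper_y0):
        with pytest.raises(ValueError, match="exceeds epsilon"):
            uh_experiment(paper_params, paper_y0, ORDER1, (0, 0),
                          epsilon=0.01, perturbation=lambda t: 0.02,
                          config=self.CFG)

    def test_refuses_vacuous_horizon_unless_overridden(self, paper_params,
                                                       paper_y0):
        long_cfg = SolverConfig(h=0.05, T=10.0)
        with pytest.raises(ConditionViolationError):
            uh_experiment(paper_params, paper_y0, ORDER1, (0, 0),
                          epsilon=0.01, perturbation=lambda t: 0.0,
                          config=long_cfg)
        with pytest.warns(UserWarning, match="vacuous"):
            uh_experiment(paper_params, paper_y0, ORDER1, (0, 0),
                          epsilon=0.01, perturbation=lambda t: 0.0,
                          config=long_cfg, allow_condition_violation=True)
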