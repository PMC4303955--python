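"""Algebraic steady states, the linear TF closed form, and calibration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mirffl import (
    CalibrationError,
    DomainError,
    Mechanism,
    Topology,
    calibrate_parameter_for_protein_ss,
    hill,
    linear_subsystem_solution,
    steady_state,
    tf_steady,
)

from conftest import ALL_VARIANTS


class TestTfSteady:
    def test_defaults(self, params):
        assert tf_steady(params) == (15.0, 300.0)

    def test_kq_sweep_endpoint(self, params):
        assert tf_steady(params.replace(kq=0.16)) == (15.0, 1200.0)

    def test_no_synthesis(self, params):
        assert tf_steady(params.replace(kw=0.0)) == (0.0, 0.0)

    def test_zero_degradation_rejected(self, params):
        with pytest.raises(DomainError):
            tf_steady(params.replace(gw=0.0))


class TestLinearSolution:
    def test_constant_at_fixed_point(self, params):
        for t in (0.0, 123.4, 5000.0):
            assert linear_subsystem_solution(params, 15.0, 300.0, t) == pytest.approx(
                (15.0, 300.0), rel=1e-12
            )

    def test_asymptotic_limit(self, params):
        w, q = linear_subsystem_solution(params, 7.5, 150.0, 1e7)
        assert (w, q) == pytest.approx((15.0, 300.0), rel=1e-9)

    @pytest.mark.parametrize("gq", [0.002, 0.004])  # distinct and confluent (gw=0.004)
    def test_matches_numerical_oracle(self, params, gq):
        p = params.replace(gq=gq)

        def f(t, y):
            return [p.kw - p.gw * y[0], p.kq * y[0] - p.gq * y[1]]

        sol = solve_ivp(f, (0, 5000), [7.5, 150.0], rtol=1e-12, atol=1e-14, dense_output=True)
        for t in (100.0, 1000.0, 5000.0):
            w, q = linear_subsystem_solution(p, 7.5, 150.0, t)
            w_ref, q_ref = sol.sol(t)
            assert w == pytest.approx(w_ref, rel=1e-8)
            assert q == pytest.approx(q_ref, rel=1e-8)

    def test_vectorized_in_t(self, params):
        t = np.array([0.0, 10.0, 100.0])
        w, q = linear_subsystem_solution(params, 7.5, 150.0, t)
        assert w.shape == q.shape == (3,)


def _damped_fixed_point_sr(ks_q, kr_q, p, iters=200_000, alpha=0.2):
    """Brute-force oracle for the dual-degradation (s*, r*) balance."""
    s, r = ks_q / p.gs, kr_q / p.gr
    for _ in range(iters):
        s_new = ks_q / (p.gs + p.krs * r)
        r_new = kr_q / (p.gr + p.krs * s)
        s += alpha * (s_new - s)
        r += alpha * (r_new - r)
    return s, r


class TestSteadyState:
    @pytest.mark.parametrize("mech, topo", ALL_VARIANTS)
    def test_residual_certificate(self, params, mech, topo):
        res = steady_state(mech, topo, params)
        assert res.residual < 1e-9
        assert all(v >= 0 for v in res.state)

    def test_stop_1in_chain_substitution(self, params):
        st = steady_state(Mechanism.STOP, Topology.IN1, params).state
        assert st.s == pytest.approx(173.0769, rel=1e-5)
        assert st.r == pytest.approx(13.84615, rel=1e-5)
        assert st.p == pytest.approx(594.2, rel=1e-3)

    @pytest.mark.parametrize("topo", list(Topology))
    def test_dual_quadratic_matches_damped_iteration(self, params, topo):
        from mirffl import production_rates

        _, q_star = tf_steady(params)
        ks_q, kr_q = production_rates(topo, params, q_star)
        s_ref, r_ref = _damped_fixed_point_sr(ks_q, kr_q, params)
        st = steady_state(Mechanism.DUAL_DEG, topo, params).state
        assert st.s == pytest.approx(s_ref, rel=1e-8)
        assert st.r == pytest.approx(r_ref, rel=1e-8)

    @pytest.mark.parametrize("topo", list(Topology))
    def test_mechanism_limits_agree(self, params, topo):
        dual0 = steady_state(Mechanism.DUAL_DEG, topo, params.replace(krs=0.0)).state
        targ0 = steady_state(Mechanism.TARGET_DEG, topo, params.replace(gmax=0.0)).state
        assert tuple(dual0) == pytest.approx(tuple(targ0), rel=1e-12)
        # Stop model with no translational repression reduces to kp*r*/gp
        stop_inf = steady_state(Mechanism.STOP, topo, params.replace(hp=1e12)).state
        assert stop_inf.p == pytest.approx(params.kp * stop_inf.r / params.gp, rel=1e-6)

    def test_stop_protein_identity(self, params):
        for topo in Topology:
            st = steady_state(Mechanism.STOP, topo, params).state
            expected = hill(st.s, params.kp, params.hp, -1, params.c) * st.r / params.gp
            assert st.p == pytest.approx(expected, rel=1e-12)

    def test_zero_degradation_rejected(self, params):
        with pytest.raises(DomainError):
            steady_state(Mechanism.STOP, Topology.IN1, params.replace(gs=0.0))


class TestCalibration:
    def test_identity_calibration(self, params):
        p_default = steady_state(Mechanism.TARGET_DEG, Topology.C1, params).state.p
        value = calibrate_parameter_for_protein_ss(
            Mechanism.TARGET_DEG, Topology.C1, params, "gmax", p_default
        )
        assert value == pytest.approx(params.gmax, rel=1e-8)

    def test_gp_scaling(self, params):
        # p* scales as 1/gp in the target-degradation mechanism
        value = calibrate_parameter_for_protein_ss(
            Mechanism.TARGET_DEG, Topology.C1, params, "gp", 2600.0
        )
        assert value == pytest.approx(0.001, rel=2e-2)
        recomputed = steady_state(
            Mechanism.TARGET_DEG, Topology.C1, params.replace(gp=value)
        ).state.p
        assert recomputed == pytest.approx(2600.0, rel=1e-8)

    def test_krs_root_postcheck(self, params):
        p_at_zero = steady_state(
            Mechanism.DUAL_DEG, Topology.C1, params.replace(krs=0.0)
        ).state.p
        target = 0.8 * p_at_zero
        value = calibrate_parameter_for_protein_ss(
            Mechanism.DUAL_DEG, Topology.C1, params, "krs", target
        )
        assert value > 0
        recomputed = steady_state(
            Mechanism.DUAL_DEG, Topology.C1, params.replace(krs=value)
        ).state.p
        assert recomputed == pytest.approx(target, rel=1e-8)

    def test_unreachable_target(self, params):
        with pytest.raises(CalibrationError):
            # krs cannot raise p* above its krs=0 ceiling
            p_ceiling = steady_state(
                Mechanism.DUAL_DEG, Topology.C1, params.replace(krs=0.0)
            ).state.p
            calibrate_parameter_for_protein_ss(
                Mechanism.DUAL_DEG, Topology.C1, params, "krs", 2.0 * p_ceiling
            )
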