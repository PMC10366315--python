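"""Coupled transient solver: building blocks and closed-form oracles."""

import numpy as np
import pytest

from tkr_ehl.ehl import (
    EHLState,
    SimulationConfig,
    cavitation_penalty,
    film_thickness,
    hertz_pressure_profile,
    load_balance_residual,
)
from tkr_ehl.elasticity import SolutionDomain

from conftest import make_solver, rigid

W_REF = 70671.0  # N/m, 2000 N over the medial length


class TestFilmThickness:
    def test_parabolic_gap_without_deflection(self):
        X = np.linspace(-2, 2, 21)
        H = film_thickness(0.0, X, np.zeros_like(X))
        np.testing.assert_allclose(H, 0.5 * X**2, rtol=1e-14)

    def test_center_value_and_offset_shift(self):
        X = np.linspace(-1, 1, 11)
        delta = np.abs(X)
        H = film_thickness(0.3, X, delta)
        assert H[5] == pytest.approx(0.3)
        np.testing.assert_allclose(film_thickness(0.8, X, delta) - H, 0.5, rtol=1e-14)


class TestCavitationPenalty:
    def test_inactive_for_nonnegative_pressure(self):
        P = np.array([0.0, 0.5, 2.0])
        assert np.all(cavitation_penalty(P, 1e4) == 0.0)

    def test_monotone_in_coefficient(self):
        P = np.array([-0.1, 0.2, -0.3])
        a = cavitation_penalty(P, 1e3)
        b = cavitation_penalty(P, 1e4)
        assert np.all(b[P < 0] < a[P < 0])

    def test_invalid_coefficient(self):
        with pytest.raises(ValueError):
            cavitation_penalty(np.zeros(3), -1.0)


class TestLoadBalance:
    def test_hertz_profile_balances_reference_load(self, smooth_setup, domain_coarse):
        s = make_solver(smooth_setup, domain_coarse)
        s.prepare(w_ref=W_REF, u_scale=0.1)
        P = hertz_pressure_profile(s.X)
        res = load_balance_residual(P, np.zeros_like(P), W_REF, s.hertz, s.X)
        # trapezoid quadrature of the edge square-root only: O(dX^(3/2))
        assert abs(res) < 5e-3

    def test_doubling_pressure_doubles_integral(self, smooth_setup, domain_coarse):
        s = make_solver(smooth_setup, domain_coarse)
        s.prepare(w_ref=W_REF, u_scale=0.1)
        P = hertz_pressure_profile(s.X)
        r1 = load_balance_residual(P, np.zeros_like(P), W_REF, s.hertz, s.X)
        r2 = load_balance_residual(2 * P, np.zeros_like(P), W_REF, s.hertz, s.X)
        assert (r2 + 1.0) == pytest.approx(2.0 * (r1 + 1.0), rel=1e-12)

    def test_zero_pressure_gives_minus_one(self, smooth_setup, domain_coarse):
        s = make_solver(smooth_setup, domain_coarse)
        s.prepare(w_ref=W_REF, u_scale=0.1)
        z = np.zeros_like(s.X)
        assert load_balance_residual(z, z, W_REF, s.hertz, s.X) == -1.0


class TestInitialization:
    def test_hertzian_reference_state(self, smooth_setup, domain_coarse):
        s = make_solver(smooth_setup, domain_coarse)
        s.prepare(w_ref=W_REF, u_scale=0.1)
        st = s.initialize_reference(W_REF)
        assert st.P.max() == pytest.approx(1.0, rel=1e-12)
        assert st.P[np.abs(s.X) >= 1.0].max() == 0.0
        assert st.H.min() > 0.0
        assert st.P_a.max() == 0.0


class TestReynoldsResidual:
    def test_flat_film_zero_pressure_is_trivial_solution(self, smooth_setup, domain_coarse):
        s = make_solver(smooth_setup, domain_coarse)
        s.prepare(w_ref=W_REF, u_scale=0.1)
        H = np.full_like(s.X, 0.5)
        P = np.zeros_like(s.X)
        R = s.reynolds_residual(P, H, Ubar=1.0)
        assert np.abs(R).max() < 1e-14

    def test_negative_time_step_rejected(self, smooth_setup, domain_coarse):
        s = make_solver(smooth_setup, domain_coarse)
        s.prepare(w_ref=W_REF, u_scale=0.1)
        with pytest.raises(ValueError):
            s.reynolds_residual(np.zeros_like(s.X), np.ones_like(s.X), dT=-1.0)


class TestRigidOracles:
    def test_pressure_peak_upstream_of_center(self, smooth_setup, domain_coarse):
        """Rigid iso-viscous wedge: the maximum sits on the inlet side."""
        s = rigid(make_solver(smooth_setup, domain_coarse, newton_tol=1e-10))
        s.prepare(w_ref=W_REF, u_scale=0.1)
        st = s.solve_steady(w=0.0, u_m=0.05, prescribed_H0=0.3)
        assert s.X[np.argmax(st.P)] < 0.0
        st_m = s.solve_steady(w=0.0, u_m=-0.05, prescribed_H0=0.3)
        assert s.X[np.argmax(st_m.P)] > 0.0

    def test_mirrored_entrainment_mirrors_solution(self, smooth_setup, domain_coarse):
        s = rigid(make_solver(smooth_setup, domain_coarse, newton_tol=1e-10))
        s.prepare(w_ref=W_REF, u_scale=0.1)
        sp = s.solve_steady(w=0.0, u_m=0.05, prescribed_H0=0.3)
        sm = s.solve_steady(w=0.0, u_m=-0.05, prescribed_H0=0.3)
        np.testing.assert_allclose(sp.P, sm.P[::-1], atol=1e-12)

    def test_pure_squeeze_matches_closed_form(self, smooth_setup):
        """Constant approach of a rigid parabolic gap: direct integration
        of the Reynolds equation with the Couette term off gives
        P = dH0/dT / (2 eps) * (1/H^2 - 1/H_end^2)."""
        s = rigid(make_solver(smooth_setup, SolutionDomain(n_contact=321), newton_tol=1e-11))
        s.prepare(w_ref=W_REF, u_scale=0.1)
        X = s.X
        H0, V, dT = 0.15, 0.01, 1e-3
        z = np.zeros_like(X)
        st = EHLState(T=0, phase=0, H0=H0, P=z.copy(), P_a=z.copy(),
                      H=film_thickness(H0, X, z), delta_bar=z.copy(), w=0, u_m=0)
        st1 = s.solve_time_step(st, 0.0, 0.0, dT, prescribed_H0=H0 - V * dT)
        st2 = s.solve_time_step(st1, 0.0, 0.0, dT, prev2=st, prescribed_H0=H0 - 2 * V * dT)
        Hx = (H0 - 2 * V * dT) + 0.5 * X**2
        P_exact = V / (2 * s.eps) * (1.0 / Hx**2 - 1.0 / Hx[-1] ** 2)
        load_err = abs(np.trapezoid(st2.P, X) / np.trapezoid(P_exact, X) - 1.0)
        assert load_err < 0.01


class TestTransient:
    def test_constant_inputs_converge_to_steady_solution(self, smooth_setup, domain):
        s = make_solver(smooth_setup, domain, newton_tol=1e-9)
        s.prepare(w_ref=W_REF, u_scale=0.15)
        steady = s.solve_steady(w=14134.0, u_m=0.15)
        st = s.initialize_reference(14134.0)
        prev2 = None
        for _ in range(250):
            st_new = s.solve_time_step(st, 14134.0, 0.15, 1.0, prev2=prev2)
            prev2, st = st, st_new
        assert np.abs(st.H - steady.H).max() / steady.H.max() < 0.005
        assert np.abs(st.P - steady.P).max() / steady.P.max() < 0.005

    def test_squeeze_term_vanishes_at_stationarity(self, smooth_setup, domain):
        s = make_solver(smooth_setup, domain, newton_tol=1e-9)
        s.prepare(w_ref=W_REF, u_scale=0.15)
        st = s.initialize_reference(14134.0)
        prev2 = None
        for _ in range(250):
            st_new = s.solve_time_step(st, 14134.0, 0.15, 1.0, prev2=prev2)
            prev2, st = st, st_new
        pois, cou, sq, pen = s._residual_terms(
            st.P, st.H, (prev2.H, st.H), (1.5, -2.0, 0.5), 1.0, 1.0
        )
        assert np.linalg.norm(sq) < 1e-3 * np.linalg.norm(cou)

    def test_transient_reversal_symmetry(self, smooth_setup, domain):
        s = make_solver(smooth_setup, domain, newton_tol=1e-10)
        s.prepare(w_ref=W_REF, u_scale=0.15)

        def march(u):
            st = s.initialize_reference(14134.0)
            prev2 = None
            for _ in range(25):
                st_new = s.solve_time_step(st, 14134.0, u, 0.5, prev2=prev2)
                prev2, st = st, st_new
            return st

        sp, sm = march(0.15), march(-0.15)
        assert np.abs(sp.P - sm.P[::-1]).max() < 1e-7
        assert np.abs(sp.H - sm.H[::-1]).max() < 1e-7


class TestGaitRun:
    def test_invariants_on_demo_run(self, demo_solutions):
        sol = demo_solutions[("S1", "medial")]
        for st in sol.states:
            assert st.H.min() > 0.0
            assert st.P.min() >= -1e-3
            assert abs(st.load_residual) < 1e-4
        assert np.all(np.isfinite(sol.lambda_min)) and np.all(sol.lambda_min > 0)

    def test_traces_recomputable_from_states(self, demo_solutions):
        sol = demo_solutions[("S1", "lateral")]
        p_max = sol.p_max.copy()
        sol.compute_traces()
        np.testing.assert_array_equal(sol.p_max, p_max)

    def test_cyclic_convergence_mode(self, s1_profile, rough_setup, domain):
        s = make_solver(
            rough_setup, domain, steps_per_cycle=60, newton_max_iter=60,
            cyclic_convergence=True, cyclic_tol=0.05, max_cycles=3,
        )
        sol = s.run_gait(s1_profile, "lateral")
        assert 1 <= sol.cycles_run <= 3
        assert np.all(np.isfinite(sol.p_max))

    def test_deterministic_rerun(self, s1_profile, rough_setup, domain):
        cfg = dict(steps_per_cycle=60, newton_max_iter=60)
        a = make_solver(rough_setup, domain, **cfg).run_gait(s1_profile, "lateral")
        b = make_solver(rough_setup, domain, **cfg).run_gait(s1_profile, "lateral")
        np.testing.assert_array_equal(a.p_max, b.p_max)
        np.testing.assert_array_equal(a.h_min, b.h_min)


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(steps_per_cycle=10)
        with pytest.raises(ValueError):
            SimulationConfig(newton_tol=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(u_scale_policy="nonsense")
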