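"""Core circuit model: coefficients, steady states, integration, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import eyeperf as ep
from eyeperf.model import build_state_space, rk4_maps
from eyeperf.params import ParameterError, compute_coefficients


class TestCoefficients:
    def test_table_values(self, eye, sys_cf):
        c = compute_coefficients(eye, sys_cf)
        assert c.alpha == pytest.approx(3.20436, abs=1e-10)
        assert c.beta == pytest.approx(38.68848, abs=1e-10)
        assert c.gamma == pytest.approx(10.736, abs=1e-10)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ParameterError):
            ep.EyeParams(trabecular_resistance=-1.0)
        with pytest.raises(ParameterError):
            ep.SystemParams(system_compliance=-0.1)

    def test_series_wall_compliance(self, eye):
        # C_W1 = C_W2 = 2 C_W gives back the measured series compliance
        assert eye.wall_compliance == pytest.approx(0.09)


class TestCharacteristicPolynomial:
    def test_flow_realization_matches_governing_equation(self, eye, sys_cf):
        """State-matrix char poly equals (a R_C C_S, a + b C_S, g, 1)."""
        A, _, _ = build_state_space(eye, sys_cf, "flow")
        c = compute_coefficients(eye, sys_cf)
        a3 = c.alpha * sys_cf.cannula_resistance * sys_cf.system_compliance
        a2 = c.alpha + c.beta * sys_cf.system_compliance
        expected = np.array([a3, a2, c.gamma, 1.0]) / a3
        np.testing.assert_allclose(np.poly(A), expected, rtol=1e-12)

    def test_gravity_realization_includes_system_resistance(self, eye, sys_cpg1):
        A, _, _ = build_state_space(eye, sys_cpg1, "gravity")
        c = compute_coefficients(eye, sys_cpg1)
        rs = sys_cpg1.system_resistance
        rc, cs = sys_cpg1.cannula_resistance, sys_cpg1.system_compliance
        rt = eye.trabecular_resistance
        a3 = c.alpha * rc * cs
        a2 = (c.alpha * rs + c.alpha * rc + c.beta * rs * cs) / rs
        a1 = (c.gamma * rs + c.beta) / rs
        a0 = (rs + rc + rt) / rs
        np.testing.assert_allclose(np.poly(A),
                                   np.array([a3, a2, a1, a0]) / a3, rtol=1e-12)


class TestRealizationEquivalenceProperty:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(rt=st.floats(1.0, 200.0), rw=st.floats(0.1, 20.0),
           cw=st.floats(0.01, 1.0), rc=st.floats(0.05, 5.0),
           cs=st.floats(0.005, 0.5))
    def test_char_poly_matches_for_any_physical_eye(self, rt, rw, cw, rc, cs):
        """The circuit realization reproduces the scalar-form coefficients
        for arbitrary physical parameter sets, not just the defaults."""
        eye = ep.EyeParams(trabecular_resistance=rt, wall_resistance=rw,
                           wall_compliance_1=2 * cw, wall_compliance_2=2 * cw)
        sysp = ep.SystemParams(cannula_resistance=rc, system_compliance=cs)
        A, _, _ = build_state_space(eye, sysp, "flow")
        c = compute_coefficients(eye, sysp)
        a3 = c.alpha * rc * cs
        expected = np.array([a3, c.alpha + c.beta * cs, c.gamma, 1.0]) / a3
        np.testing.assert_allclose(np.poly(A), expected, rtol=1e-8)


class TestSteadyState:
    @pytest.mark.parametrize("mode,gain,level,f_exp,p_exp", [
        ("CPg", 10.0, 20.0, 0.09370, 19.0630),
        ("CPp", 7.0, 20.0, 0.11493, 19.9836),
    ])
    def test_closed_form_plateaus(self, eye, mode, gain, level, f_exp, p_exp):
        from tests.conftest import system_for
        ss = ep.steady_state(mode, level, eye, system_for(mode, gain))
        assert ss.f_s == pytest.approx(f_exp, abs=5e-5)
        assert ss.p_s == pytest.approx(p_exp, abs=5e-4)
        assert ss.f_e == ss.f_s
        assert ss.p_e == pytest.approx(ss.p_s - 0.36 * ss.f_s)

    def test_resting_equilibrium(self, eye, sys_cf):
        ss = ep.steady_state("CF", 0.0, eye, sys_cf)
        assert ss == (15.0, 0.0, 15.0, 0.0)

    def test_flow_nearly_equal_across_modes(self, eye):
        """Matched plateau pressures need nearly identical steady flows."""
        f_cf = ep.steady_state("CF", 0.115, eye, ep.SystemParams()).f_s
        f_g = ep.steady_state("CPg", 20.0, eye,
                              ep.SystemParams(system_resistance=0.6)).f_s
        f_p = ep.steady_state("CPp", 20.0, eye,
                              ep.SystemParams(feedback_gain=7.0)).f_s
        assert max(f_cf, f_g, f_p) / min(f_cf, f_g, f_p) < 1.02


class TestIntegration:
    def test_fixed_point_at_rest(self, eye, sys_cf):
        tr = ep.integrate("CF", 0.0, eye, sys_cf, duration_min=5.0)
        np.testing.assert_allclose(tr.p_s, 15.0, atol=1e-10)
        np.testing.assert_allclose(tr.f_e, 0.0, atol=1e-10)

    def test_cf_step_reaches_plateau(self, eye, sys_cf):
        tr = ep.integrate("CF", 0.1, eye, sys_cf, duration_min=150.0)
        assert tr.p_s[-1] == pytest.approx(19.336, abs=1e-4)

    def test_cpp_terminal_flow_matches_closed_form(self, eye, sys_cpp):
        tr = ep.integrate("CPp", 20.0, eye, sys_cpp, duration_min=60.0)
        ss = ep.steady_state("CPp", 20.0, eye, sys_cpp)
        assert tr.f_s[-1] == pytest.approx(ss.f_s, rel=1e-6)

    @pytest.mark.parametrize("mode,gain,level", [
        ("CF", None, 0.1), ("CPg", 0.6, 20.0), ("CPp", 7.0, 20.0)])
    def test_flow_conservation(self, eye, mode, gain, level):
        """F_E = F_S - C_S dP_S/dt at interior samples, to O(dt^2)."""
        from tests.conftest import system_for
        sysp = system_for(mode, gain)
        tr = ep.integrate(mode, level, eye, sysp, duration_min=10.0)
        dps = np.gradient(tr.p_s, tr.dt_min)
        fe = tr.f_s - sysp.system_compliance * dps
        # skip onset where the pump flow is discontinuous
        i0 = int(1.0 / tr.dt_min)
        np.testing.assert_allclose(fe[i0:-1], tr.f_e[i0:-1], atol=2e-3)

    def test_rk4_terminal_converged_in_dt(self, eye, sys_cpg2):
        a = ep.integrate("CPg", 20.0, eye, sys_cpg2, 60.0, dt_s=0.1)
        b = ep.integrate("CPg", 20.0, eye, sys_cpg2, 60.0, dt_s=0.05)
        assert abs(a.p_s[-1] - b.p_s[-1]) < 1e-8

    def test_purely_elastic_limit_matches_analytic(self, sys_cf):
        """R_W = 0 drops the order; RK4 matches the matrix exponential."""
        eye0 = ep.EyeParams(wall_resistance=0.0)
        dt_s = 0.02
        tr = ep.integrate("CF", 0.1, eye0, sys_cf, duration_min=30.0, dt_s=dt_s)
        A, B, c = build_state_space(eye0, sys_cf, "flow")
        x0 = np.array([15.0, 0.0, 15.0])
        d = B * 0.1 + c
        # affine analytic solution via the augmented exponential
        M = np.zeros((4, 4))
        M[:3, :3] = A
        M[:3, 3] = d
        t = (np.arange(len(tr)) + 1) * dt_s / 60.0
        ref = np.array([(expm(M * ti) @ np.concatenate([x0, [1.0]]))[0]
                        for ti in t[::500]])
        np.testing.assert_allclose(tr.p_s[::500], ref, rtol=1e-6)

    def test_divergence_reported_with_time(self, eye):
        # an absurd digital gain destabilizes the 0.1-s feedback loop
        sysp = ep.SystemParams(feedback_gain=5e4)
        with pytest.raises(ep.SimulationDiverged):
            ep.integrate("CPp", 20.0, eye, sysp, duration_min=30.0)

    def test_gravity_pump_equivalence(self, eye, sys_cpg1):
        """Analog pump with K = 1/R_S reproduces the gravity trace exactly."""
        t1 = ep.integrate("CPg", 20.0, eye, sys_cpg1, 30.0)
        t2 = ep.integrate("CPp", 20.0, eye, ep.SystemParams(feedback_gain=0.1),
                          30.0, analog=True)
        assert np.max(np.abs(t1.p_s - t2.p_s)) < 1e-6


class TestRecoverEyeState:
    def test_constant_trace(self, sys_cf):
        p = np.full(100, 17.0)
        f = np.zeros(100)
        pe, fe = ep.recover_eye_state(p, f, sys_cf, dt_s=0.1)
        np.testing.assert_allclose(pe, 17.0)
        np.testing.assert_allclose(fe, 0.0)

    def test_plateau_of_simulated_step(self, eye, sys_cf):
        tr = ep.integrate("CF", 0.1, eye, sys_cf, duration_min=150.0)
        pe, fe = ep.recover_eye_state(tr.p_s, tr.f_s, sys_cf, tr.sample_period)
        assert pe[-10] == pytest.approx(tr.p_s[-10] - 0.36 * 0.1, abs=1e-6)
        assert fe[-10] == pytest.approx(0.1, abs=1e-6)

    def test_linear_ramp_gives_exact_compliance_flow(self, sys_cf):
        r = 0.5  # mmHg/min
        t = np.arange(600) * (0.1 / 60.0)
        pe, fe = ep.recover_eye_state(15.0 + r * t, np.zeros_like(t),
                                      sys_cf, dt_s=0.1)
        np.testing.assert_allclose(fe[1:-1], -sys_cf.system_compliance * r,
                                   rtol=1e-9)

    def test_too_short_series_rejected(self, sys_cf):
        with pytest.raises(ValueError):
            ep.recover_eye_state(np.array([15.0]), np.array([0.0]), sys_cf, 0.1)


class TestModelState:
    def test_scalar_view_roundtrip(self, eye, sys_cf):
        state = ep.ModelState(0.0, np.array([17.0, 0.4, 16.1]))
        ps, dps, d2ps = state.scalar_view(eye, sys_cf, u=0.1)
        back = ep.ModelState.from_scalar(ps, dps, d2ps, eye, sys_cf, u=0.1)
        np.testing.assert_allclose(back.x, state.x, rtol=1e-9)


class TestSettlingTime:
    def test_single_exponential_analytic(self, eye, sys_cf):
        """Settling of a pure exponential is tau * ln(1/0.01)."""
        dt_s = 0.1
        tau = 2.0
        t = (np.arange(int(30 / (dt_s / 60))) + 1) * dt_s / 60.0
        p = 20.0 - 5.0 * np.exp(-t / tau)
        tr = ep.Trace(dt_s, p, np.full_like(p, 0.1), p, np.full_like(p, 0.1))
        plat = ep.SteadyState(20.0, 0.1, 20.0, 0.1)
        pre = ep.SteadyState(15.0, 0.1, 15.0, 0.1)
        got = ep.settling_time(tr, plat, pre)
        assert got == pytest.approx(tau * np.log(100.0), abs=0.01)

    def test_unsettled_trace_returns_nan(self, eye, sys_cf):
        tr = ep.integrate("CF", 0.1, eye, sys_cf, duration_min=5.0)
        plat = ep.steady_state("CF", 0.1, eye, sys_cf)
        pre = ep.steady_state("CF", 0.0, eye, sys_cf)
        assert np.isnan(ep.settling_time(tr, plat, pre))

    def test_gain_monotonicity(self, eye):
        """Noise-free settling time never increases with feedback gain."""
        df = ep.gain_sweep("CPg", [10.0, 1.0, 0.1], eye)
        s = df.sort_values("gain", ascending=False)["settling_min"].to_numpy()
        assert np.all(np.diff(s) <= 1e-9)


class TestTraceIO:
    def test_csv_roundtrip(self, eye, sys_cf, tmp_path):
        tr = ep.integrate("CF", 0.1, eye, sys_cf, duration_min=2.0)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = ep.Trace.from_csv(path)
        np.testing.assert_allclose(back.p_s, tr.p_s)
        np.testing.assert_allclose(back.f_e, tr.f_e)
        assert back.sample_period == pytest.approx(tr.sample_period)
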