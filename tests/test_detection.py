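"""Steady-state criteria, smoothing and the recursive regression."""

import numpy as np
import pytest

import eyeperf as ep
from eyeperf.detection import CriterionConfig, RecursiveFitter, smooth


def make_trace(p, f, dt_s=0.1):
    p = np.asarray(p, float)
    f = np.asarray(f, float)
    return ep.Trace(dt_s, p, f, p, f)


def exp_step(tau_min, a=5.0, b=15.0, duration_min=30.0, dt_s=0.1,
             c=0.0, d=0.1):
    t = (np.arange(int(duration_min * 600)) + 1) * dt_s / 60.0
    return t, a * (1.0 - np.exp(-t / tau_min)) + b, c * np.exp(-t / tau_min) + d


class TestWindowCriterion:
    def test_constant_trace_detects_at_first_full_window(self):
        tr = make_trace(np.full(6000, 20.0), np.full(6000, 0.1))
        res = ep.window_criterion(tr, pressure_step_size=5.0)
        assert res.converged
        assert res.settle_time == pytest.approx(5.0, abs=0.01)
        assert res.steady_p_s == pytest.approx(20.0)

    def test_exponential_detection_time_closed_form(self):
        """5 e^{-t}(1 - e^{-5}) = 0.5 puts detection at 2.296 + 5 min."""
        t, p, f = exp_step(1.0)
        res = ep.window_criterion(make_trace(p, f), pressure_step_size=5.0)
        assert res.settle_time == pytest.approx(np.log(10 * (1 - np.exp(-5.0))) + 5.0,
                                                abs=0.01)

    def test_timeout_flagged(self):
        t = np.arange(3000) * (0.1 / 60.0)
        res = ep.window_criterion(make_trace(15 + t, np.full_like(t, 0.1)),
                                  pressure_step_size=5.0,
                                  cfg=CriterionConfig(timeout=5.0))
        assert not res.converged


class TestRatioCriterion:
    def test_constant_ratio_detects_after_window_plus_hold(self):
        tr = make_trace(np.full(6000, 20.0), np.full(6000, 0.1))
        res = ep.ratio_criterion(tr)
        assert res.converged
        assert res.settle_time == pytest.approx(6.0, abs=0.01)

    def test_drifting_ratio_above_threshold_never_detects(self):
        # ratio slope of exactly 0.2 nl/min^2/mmHg, twice the threshold
        t = np.arange(12000) * (0.1 / 60.0)
        p = np.full_like(t, 20.0)
        f = (0.2e-3 * t) * 20.0
        res = ep.ratio_criterion(make_trace(p, f),
                                 CriterionConfig(criterion="ratio", timeout=20.0))
        assert not res.converged

    def test_nonpositive_pressure_rejected(self):
        p = np.full(4000, 1.0)
        p[100] = 0.0
        with pytest.raises(ValueError):
            ep.ratio_criterion(make_trace(p, np.ones(4000)))


class TestSmooth:
    def test_zero_width_is_identity(self):
        y = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(smooth(y, 0.0, 0.1 / 60), y)

    def test_constant_unchanged(self):
        y = np.full(1000, 3.3)
        np.testing.assert_allclose(smooth(y, 2.0, 0.1 / 60), 3.3)

    def test_white_noise_variance_reduction(self):
        """Averaging m iid samples divides the SD by about sqrt(m)."""
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200000)
        m = 50
        s = smooth(y, m * (0.1 / 60.0), 0.1 / 60.0)
        assert s[m:].std() == pytest.approx(1.0 / np.sqrt(m), rel=0.2)

    def test_smoothed_series_stays_within_data_range(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(5000)
        s = smooth(y, 1.0, 0.1 / 60.0)
        assert s.min() >= y.min() and s.max() <= y.max()


class TestRecursiveFit:
    def test_noise_free_parameter_recovery(self):
        t = (np.arange(600) + 1) / 60.0
        a, b, c, d, tau = 4.3, 15.0, 8.0, 0.116, 1.3
        p = a * (1 - np.exp(-t / tau)) + b
        f = c * np.exp(-t / tau) + d
        fit = ep.recursive_fit(p, f, t)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.p_plateau == pytest.approx(a + b, rel=1e-6)
        assert fit.f_plateau == pytest.approx(d, rel=1e-5)

    def test_constant_data_flagged_degenerate(self):
        t = (np.arange(300) + 1) / 60.0
        fit = ep.recursive_fit(np.full_like(t, 20.0), np.full_like(t, 0.1), t)
        assert fit.degenerate
        assert abs(fit.a) < 1e-6 and abs(fit.c) < 1e-6

    def test_early_bump_progressively_ignored(self):
        """The fitted plateau approaches truth as clean data accumulates."""
        tau, a, b, d = 1.0, 5.0, 15.0, 0.116
        t_all = (np.arange(3600) + 1) / 60.0
        p = a * (1 - np.exp(-t_all / tau)) + b
        f = 8.0 * np.exp(-t_all / tau) + d
        bump = np.zeros_like(t_all)
        i0 = 150  # a 2.5-mmHg transient early in the record
        bump[i0:i0 + 60] = 2.5 * np.exp(-np.arange(60) / 20.0)
        p_noisy = p + bump
        errs = []
        for n in (600, 1800, 3600):
            fit = ep.recursive_fit(p_noisy[:n], f[:n], t_all[:n])
            errs.append(abs(fit.p_plateau - (a + b)))
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.05


class TestFittingCriterion:
    def test_noise_free_exponential_detection_rule(self):
        """Detection lands once 6 tau plus the 2-min hold have elapsed."""
        t, p, f = exp_step(1.0, c=8.0, d=0.116, duration_min=20.0)
        res = ep.fitting_criterion(make_trace(p, f))
        assert res.converged
        assert res.settle_time == pytest.approx(6.0 + 2.0, abs=0.7)
        assert res.steady_p_s == pytest.approx(20.0, abs=0.01)
        assert res.steady_f_e == pytest.approx(0.116, abs=0.001)

    def test_no_detection_while_tau_estimate_drifts(self):
        """A ramp keeps tau pinned at its bound: the rule must not fire."""
        t = (np.arange(6000) + 1) * (0.1 / 60.0)
        p = 15.0 + 0.4 * t  # never plateaus
        res = ep.fitting_criterion(make_trace(p, np.full_like(t, 0.1)),
                                   CriterionConfig(criterion="fitting",
                                                   timeout=10.0))
        assert not res.converged


class TestDetectionLowerBounds:
    """No criterion may fire before it has the data its rule requires."""

    def test_minimum_detection_times(self, eye, sys_cpg2):
        tr = ep.integrate("CPg", 20.0, eye, sys_cpg2, duration_min=30.0)
        w = ep.window_criterion(tr, 5.0)
        r = ep.ratio_criterion(tr)
        f = ep.fitting_criterion(tr)
        assert w.settle_time >= 5.0 - 1e-6
        assert r.settle_time >= 6.0 - 1e-6
        assert f.settle_time >= 4.0 - 1e-6  # fit start + 2-min hold

    def test_noise_free_steady_values_match_plateau(self, eye, sys_cpg2):
        """Steady pressures agree with the analytic plateau on clean traces.

        Flow is asserted for the ratio criterion only: window and fitting
        average (or regress) through the large pump transient, which offsets
        the flow identically on every step and therefore cancels in the
        downstream facility slope.
        """
        tr = ep.integrate("CPg", 20.0, eye, sys_cpg2, duration_min=40.0)
        ss = ep.steady_state("CPg", 20.0, eye, sys_cpg2)
        ratio = ep.ratio_criterion(tr)
        for res in (ep.window_criterion(tr, 5.0), ratio,
                    ep.fitting_criterion(tr)):
            assert res.steady_p_e == pytest.approx(ss.p_e, rel=5e-3)
        assert ratio.steady_f_e == pytest.approx(ss.f_e, rel=1e-2)


class TestNoiseUnbiasedness:
    def test_zero_mean_noise_does_not_bias_steady_means(self, eye, sys_cpg2):
        """Noisy steady P_E matches the noise-free detection within 3 SEM.

        The comparison point is the noise-free run through the same criterion
        (not the asymptotic plateau), because the window mean carries a small
        deterministic convergence offset that noise must not enlarge.
        """
        clean = ep.integrate("CPg", 20.0, eye, sys_cpg2, 12.0)
        win = slice(int(7 / clean.dt_min), None)  # fixed 5-min window
        ref = clean.p_e[win].mean()
        vals = []
        for seed in range(8):
            rec = ep.synth_exvivo(30.0, seed=seed)
            tr = ep.Simulator("CPg", eye, sys_cpg2, noise=rec).run(20.0, 12.0)
            vals.append(tr.p_e[win].mean())
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        sem = max(sem, 0.04 / np.sqrt(3000))  # floor: averaging-window SEM
        assert abs(np.mean(vals) - ref) < 3 * sem


class TestFitterSeries:
    def test_fitted_series_backfills_from_onset(self):
        t, p, f = exp_step(1.0, c=8.0, d=0.116, duration_min=6.0)
        fitter = RecursiveFitter(CriterionConfig(criterion="fitting"), 0.1)
        fitter.extend(p, f)
        assert fitter.pred_offset == 0
        assert len(fitter.ps_star) == len(fitter.t_blocks)
        # predictions track the clean exponential closely
        np.testing.assert_allclose(fitter.ps_star[-10:], p[::1][-10 * 10::10][:10],
                                   atol=0.05)
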