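"""PAM fluorescence parameters and Platt rapid-light-curve fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from algafuel.photosynthesis import (
    RapidLightCurve,
    effective_qy,
    fit_platt,
    max_quantum_yield,
    platt_retr,
    platt_retr_max,
    quenching,
    rel_etr,
    stress_course_summary,
)
from algafuel.synthetic_data import DEFAULT_PAR_STEPS, RLCConfig, simulate_rlc


class TestQuantumYields:
    def test_fv_fm_value(self):
        assert max_quantum_yield(260.0, 1000.0) == pytest.approx(0.74)

    def test_fv_fm_scale_invariance(self):
        assert max_quantum_yield(0.3, 1.0) == pytest.approx(0.7)
        assert max_quantum_yield(300.0, 1000.0) == pytest.approx(0.7)

    def test_zero_variable_fluorescence_rejected(self):
        with pytest.raises(ValueError):
            max_quantum_yield(500.0, 500.0)
        with pytest.raises(ValueError):
            max_quantum_yield(-1.0, 500.0)

    def test_effective_qy(self):
        assert effective_qy(0.4, 0.8) == pytest.approx(0.5)
        assert effective_qy(0.8, 0.8) == 0.0  # all centers closed

    def test_effective_qy_rejects_f_above_fm_prime(self):
        with pytest.raises(ValueError):
            effective_qy(0.9, 0.8)


class TestQuenching:
    def test_dark_state(self):
        """In the dark-adapted state (Fm' = Fm, F = F0): NPQ = 0, qP = 1."""
        result = quenching(f0=200, fm=1000, f=200, fm_prime=1000)
        assert result.npq == pytest.approx(0.0)
        assert result.qp == pytest.approx(1.0)

    def test_npq_of_halved_fm_prime(self):
        result = quenching(f0=200, fm=1000, f=300, fm_prime=500)
        assert result.npq == pytest.approx(1.0)

    def test_measured_f0_prime_is_used_verbatim(self):
        est = quenching(f0=200, fm=1000, f=300, fm_prime=500)
        meas = quenching(f0=200, fm=1000, f=300, fm_prime=500,
                         f0_prime=150.0)
        assert est.f0_prime_estimated and not meas.f0_prime_estimated
        assert meas.qp == pytest.approx((500 - 300) / (500 - 150))

    @given(st.floats(0.05, 0.4), st.floats(0.45, 1.0), st.floats(0.0, 1.0))
    def test_qp_bounded_on_valid_states(self, f0_frac, fmp_frac, f_frac):
        """qP stays in [0, 1] across random valid fluorescence states."""
        fm = 1000.0
        f0 = f0_frac * fm
        fm_prime = fmp_frac * fm
        # under actinic light F lies between F0 and Fm'
        f = f0 + f_frac * (fm_prime - f0)
        result = quenching(f0=f0, fm=fm, f=f, fm_prime=fm_prime)
        assert -1e-9 <= result.qp <= 1 + 1e-9


class TestRelEtr:
    @pytest.mark.parametrize(
        "par, qy, a, expected",
        [(0.0, 0.7, 1.0, 0.0), (100.0, 0.5, 1.0, 25.0),
         (100.0, 0.5, 0.84, 21.0)],
    )
    def test_values(self, par, qy, a, expected):
        assert rel_etr(par, qy, a) == pytest.approx(expected)

    def test_bounds(self):
        with pytest.raises(ValueError):
            rel_etr(-1.0, 0.5)
        with pytest.raises(ValueError):
            rel_etr(10.0, 1.5)


class TestPlattFit:
    def test_noiseless_round_trip(self):
        """Parameters of a noise-free synthetic curve are recovered to
        1e-6 relative."""
        truth = RLCConfig(alpha=0.3, ps=80.0, beta=0.01, noise_sd=0.0)
        fit = fit_platt(simulate_rlc(truth, seed=0).curve())
        assert fit.converged
        assert fit.alpha == pytest.approx(truth.alpha, rel=1e-6)
        assert fit.ps == pytest.approx(truth.ps, rel=1e-6)
        assert fit.beta == pytest.approx(truth.beta, rel=1e-4, abs=1e-8)
        assert fit.retr_max == pytest.approx(
            platt_retr_max(truth.alpha, truth.ps, truth.beta), rel=1e-6)

    def test_beta_zero_curve_saturates_at_ps(self):
        par = np.array(DEFAULT_PAR_STEPS, dtype=float)
        retr = platt_retr(par, 0.25, 60.0, 0.0)
        qy = np.where(par > 0, 2 * retr / np.maximum(par, 1), 0.5)
        fit = fit_platt(RapidLightCurve(par=par, qy=qy))
        assert fit.retr_max == pytest.approx(fit.ps, rel=1e-6)
        # the fitted curve is increasing and below Ps everywhere
        curve = platt_retr(par, fit.alpha, fit.ps, fit.beta)
        assert np.all(np.diff(curve) > 0)
        assert np.all(curve <= fit.ps + 1e-9)

    def test_ik_identity(self):
        """Ik * alpha == rETRmax by construction, for any fit."""
        for seed in range(5):
            fit = fit_platt(simulate_rlc(RLCConfig(), seed=seed).curve())
            assert fit.ik * fit.alpha == pytest.approx(fit.retr_max,
                                                       rel=1e-12)

    def test_retr_zero_at_zero_par(self):
        fit = fit_platt(simulate_rlc(RLCConfig(noise_sd=0.0), 0).curve())
        assert platt_retr(0.0, fit.alpha, fit.ps, fit.beta) == 0.0

    def test_mqy_is_first_step_yield(self):
        syn = simulate_rlc(RLCConfig(noise_sd=0.0), seed=0)
        fit = fit_platt(syn.curve())
        assert fit.mqy == syn.qy[0]

    def test_too_few_steps_rejected(self):
        curve = RapidLightCurve(par=np.array([0.0, 50, 100, 200]),
                                qy=np.array([0.6, 0.5, 0.4, 0.3]))
        with pytest.raises(ValueError, match="at least 5"):
            fit_platt(curve)

    def test_fluorescence_rescaling_invariance(self):
        """Fits are invariant to the (arbitrary) fluorescence unit because
        quantum yields are ratios."""
        syn = simulate_rlc(RLCConfig(), seed=11)
        base = fit_platt(RapidLightCurve.from_fluorescence(
            syn.par, syn.f, syn.fm_prime))
        scaled = fit_platt(RapidLightCurve.from_fluorescence(
            syn.par, 37.5 * syn.f, 37.5 * syn.fm_prime))
        assert scaled.alpha == pytest.approx(base.alpha, rel=1e-6)
        assert scaled.retr_max == pytest.approx(base.retr_max, rel=1e-6)
        assert scaled.ik == pytest.approx(base.ik, rel=1e-6)

    def test_matches_refined_grid_search(self):
        """Least squares beats (or ties) a twice-refined brute-force grid
        search within 1 % RSS on small instances."""
        def grid_rss(par, retr, alpha, ps, beta):
            return float(np.sum((platt_retr(par, alpha, ps, beta)
                                 - retr) ** 2))

        rng = np.random.default_rng(3)
        for case in range(10):
            truth = RLCConfig(
                alpha=float(rng.uniform(0.15, 0.45)),
                ps=float(rng.uniform(40, 120)),
                beta=float(rng.uniform(0.0, 0.05)),
                noise_sd=0.05,
            )
            syn = simulate_rlc(truth, seed=100 + case)
            curve = syn.curve()
            fit = fit_platt(curve)
            # grid search refined twice around the best cell
            lo = np.array([0.05, 20.0, 0.0])
            hi = np.array([0.8, 200.0, 0.1])
            best = None
            for _ in range(3):
                axes = [np.linspace(l, h, 12) for l, h in zip(lo, hi)]
                for a, p, b in itertools.product(*axes):
                    rss = grid_rss(curve.par, curve.retr, a, p, b)
                    if best is None or rss < best[0]:
                        best = (rss, a, p, b)
                centre = np.array(best[1:])
                span = (hi - lo) / 6
                lo = np.maximum(centre - span, [1e-3, 1.0, 0.0])
                hi = centre + span
            assert fit.rss <= best[0] * 1.01

    def test_noisy_parameter_recovery(self):
        """Median relative errors over 200 noisy curves: alpha and rETRmax
        within 10 %, Ik within 15 %."""
        truth = RLCConfig()  # 5 % multiplicative noise by default
        true_rmax = platt_retr_max(truth.alpha, truth.ps, truth.beta)
        true_ik = true_rmax / truth.alpha
        errs = {"alpha": [], "retr_max": [], "ik": []}
        for seed in range(200):
            fit = fit_platt(simulate_rlc(truth, seed=seed).curve())
            errs["alpha"].append(abs(fit.alpha - truth.alpha) / truth.alpha)
            errs["retr_max"].append(abs(fit.retr_max - true_rmax) / true_rmax)
            errs["ik"].append(abs(fit.ik - true_ik) / true_ik)
        assert np.median(errs["alpha"]) <= 0.10
        assert np.median(errs["retr_max"]) <= 0.10
        assert np.median(errs["ik"]) <= 0.15


class TestStressSummary:
    def _frame(self, values, step=5.0):
        times = np.arange(len(values)) * step
        return pd.DataFrame({"time_min": times, "fv_fm": values})

    def test_flat_series_has_no_change_point(self):
        summary = stress_course_summary(self._frame([0.7] * 10))
        course = summary.courses["fv_fm"]
        assert course.time_of_min is None and course.recovery_time is None

    def test_v_shape_min_and_recovery(self):
        """A dip bottoming at 60 min that re-enters the 5 % band at 155 min
        is summarized as (min=60, recovery=155)."""
        times = np.arange(0.0, 241.0, 5.0)
        values = np.interp(times, [0, 10, 60, 155, 240],
                           [0.70, 0.70, 0.45, 0.67, 0.70])
        frame = pd.DataFrame({"time_min": times, "fv_fm": values})
        course = stress_course_summary(frame).courses["fv_fm"]
        assert course.time_of_min == 60.0
        assert course.recovery_time == 155.0

    def test_monotone_decline_never_recovers(self):
        course = stress_course_summary(
            self._frame(np.linspace(0.7, 0.3, 20))).courses["fv_fm"]
        assert course.time_of_min == 95.0  # the last sample
        assert course.recovery_time is None

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            stress_course_summary(self._frame([0.7, 0.6]))
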