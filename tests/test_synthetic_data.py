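"""Generators: determinism, ground-truth consistency, model structure."""

import numpy as np
import pandas as pd
import pytest

from algafuel.culture_productivity import detect_steady_state, select_optimum
from algafuel.fame_profile import saturation_summary
from algafuel.io import SCHEMAS
from algafuel.photosynthesis import fit_platt, stress_course_summary
from algafuel.synthetic_data import (
    ChemostatConfig,
    FameConfig,
    RLCConfig,
    StressConfig,
    average_irradiance,
    growth_rate,
    simulate_chemostat_sweep,
    simulate_fame_profile,
    simulate_rlc,
    simulate_stress_course,
    steady_state_biomass,
)

D_GRID = tuple(np.round(np.arange(0.05, 0.91, 0.05), 2))


class TestChemostat:
    @staticmethod
    def _mu_of_x(x, cfg):
        """Independent vectorized oracle for mu(Iav(X))."""
        tau = cfg.ka * x * cfg.light_path
        iav = np.where(tau < 1e-12, cfg.i0,
                       cfg.i0 * -np.expm1(-tau) / np.maximum(tau, 1e-300))
        ratio = (iav / cfg.ik_growth) ** cfg.hill_n
        return cfg.mu_max * ratio / (1.0 + ratio)

    def test_solver_agrees_with_dense_grid_scan(self):
        """Bisection matches a ~1e6-point grid scan to |dX| < 1e-6 g/L on
        random parameter sets."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            cfg = ChemostatConfig(
                mu_max=float(rng.uniform(0.5, 1.5)),
                ka=float(rng.uniform(100, 400)),
                light_path=float(rng.uniform(0.03, 0.15)),
                i0=float(rng.uniform(400, 1500)),
                ik_growth=float(rng.uniform(100, 500)),
                hill_n=float(rng.uniform(1.0, 2.5)),
                noise_cv=0.0,
            )
            d = float(rng.uniform(0.05, 0.9 * self._mu_of_x(0.0, cfg)))
            x = steady_state_biomass(d, cfg)
            # coarse scan over the bracket, then a dense scan of the best cell
            coarse = np.linspace(1e-9, 50.0, 10_000)
            idx = int(np.argmin(np.abs(self._mu_of_x(coarse, cfg) - d)))
            lo, hi = coarse[max(idx - 1, 0)], coarse[min(idx + 1, 9_999)]
            dense = np.linspace(lo, hi, 1_000_000)
            best = float(dense[int(np.argmin(
                np.abs(self._mu_of_x(dense, cfg) - d)))])
            assert x > 0.0
            assert abs(x - best) < 1e-6

    def test_washout_for_d_at_mu_of_full_light(self):
        cfg = ChemostatConfig(noise_cv=0.0)
        d_crit = growth_rate(cfg.i0, cfg)
        assert steady_state_biomass(d_crit + 1e-6, cfg) == 0.0
        assert steady_state_biomass(d_crit - 1e-3, cfg) < 0.01

    def test_noise_free_steady_states_decrease_with_d(self):
        cfg = ChemostatConfig(noise_cv=0.0)
        xs = [steady_state_biomass(d, cfg) for d in D_GRID]
        grown = [x for x in xs if x > 0]
        assert all(b < a for a, b in zip(grown, grown[1:]))

    def test_biomass_productivity_unimodal(self):
        """P_b = D * X_ss rises then falls over the default grid (flat only
        in the washed-out tail, where it is zero)."""
        cfg = ChemostatConfig(noise_cv=0.0)
        p_b = [d * steady_state_biomass(d, cfg) for d in D_GRID]
        peak = int(np.argmax(p_b))
        assert 0 < peak < len(p_b) - 1
        assert all(b > a for a, b in zip(p_b[: peak + 1], p_b[1: peak + 1]))
        tail = p_b[peak:]
        assert all(b < a or b == 0.0 for a, b in zip(tail, tail[1:]))

    def test_sweep_determinism(self):
        a = simulate_chemostat_sweep(ChemostatConfig(), D_GRID[:6], seed=5)
        b = simulate_chemostat_sweep(ChemostatConfig(), D_GRID[:6], seed=5)
        pd.testing.assert_frame_equal(a.timeseries_frame(),
                                      b.timeseries_frame())
        assert a.true_x_ss == b.true_x_ss

    def test_sweep_series_support_steady_state_detection(self):
        sweep = simulate_chemostat_sweep(ChemostatConfig(noise_cv=0.0),
                                         [0.1, 0.3, 0.6], seed=0)
        for ts, x_true in zip(sweep.timeseries, sweep.true_x_ss):
            window = detect_steady_state(ts)
            assert window.mean_biomass == pytest.approx(x_true, rel=0.02)

    def test_optimum_recovery_within_one_grid_step(self):
        """The grid optimum of the noise-free sweep sits within one grid
        step of the model's continuous productivity maximum."""
        cfg = ChemostatConfig(noise_cv=0.0)
        sweep = simulate_chemostat_sweep(cfg, D_GRID, seed=0)
        d_opt, _ = select_optimum(sweep.true_records(), "biomass")
        dense = np.linspace(0.01, cfg.mu_max, 2000)
        p_dense = [d * steady_state_biomass(float(d), cfg) for d in dense]
        d_true = float(dense[int(np.argmax(p_dense))])
        step = D_GRID[1] - D_GRID[0]
        assert abs(d_opt - d_true) <= step + 1e-9

    def test_generated_frame_validates_against_schema(self):
        sweep = simulate_chemostat_sweep(ChemostatConfig(), [0.2, 0.4],
                                         seed=1)
        frame = sweep.timeseries_frame().astype(str)
        validated = SCHEMAS["timeseries"].validate(frame)
        assert len(validated) == len(frame)


class TestRLCGenerator:
    def test_noiseless_round_trip(self):
        cfg = RLCConfig(noise_sd=0.0)
        fit = fit_platt(simulate_rlc(cfg, seed=0).curve())
        assert fit.alpha == pytest.approx(cfg.alpha, rel=1e-6)
        assert fit.ps == pytest.approx(cfg.ps, rel=1e-6)

    def test_zero_par_step_has_zero_retr(self):
        syn = simulate_rlc(RLCConfig(), seed=2)
        assert syn.retr[syn.par == 0] == pytest.approx(0.0)

    def test_determinism(self):
        a = simulate_rlc(RLCConfig(), seed=9)
        b = simulate_rlc(RLCConfig(), seed=9)
        assert np.array_equal(a.retr, b.retr)
        assert np.array_equal(a.f, b.f)

    def test_fluorescence_realizes_implied_yields(self):
        syn = simulate_rlc(RLCConfig(), seed=3)
        qy = (syn.fm_prime - syn.f) / syn.fm_prime
        assert qy == pytest.approx(syn.qy, abs=1e-12)

    def test_inconsistent_parameters_rejected(self):
        # enormous alpha implies QY > 1 at low light
        with pytest.raises(ValueError, match="fluorescence bounds"):
            simulate_rlc(RLCConfig(alpha=0.8), seed=0)

    def test_generated_frame_validates_against_schema(self):
        frame = simulate_rlc(RLCConfig(), seed=0).frame("s").astype(str)
        assert len(SCHEMAS["rlc"].validate(frame)) == len(frame)


class TestStressGenerator:
    def test_heat_recovery_time_detected(self):
        sc = simulate_stress_course(StressConfig(recovery_time_min=155.0),
                                    "heat38", seed=0)
        course = stress_course_summary(sc.course).courses["fv_fm"]
        assert course.time_of_min == sc.truth["fv_fm_min_time"]
        assert abs(course.recovery_time - 155.0) <= 5.0  # one sample

    def test_highlight_drops_within_five_minutes(self):
        sc = simulate_stress_course(StressConfig(), "highlight1600", seed=0)
        fv = sc.course["fv_fm"].to_numpy()
        t = sc.course["time_min"].to_numpy()
        assert fv[t == 5.0] < 0.95 * fv[0]

    def test_cold_alpha_declines_then_rebounds(self):
        sc = simulate_stress_course(StressConfig(), "cold10", seed=0)
        course = stress_course_summary(sc.course).courses["alpha"]
        assert course.time_of_min == sc.truth["alpha_min_time"]
        assert course.recovery_time is None  # rebound stays below the band

    def test_zero_noise_flat_reference_has_no_change_point(self):
        sc = simulate_stress_course(StressConfig(), "heat38", seed=0)
        flat = sc.course.copy()
        flat["fv_fm"] = flat["fv_fm"].iloc[0]
        course = stress_course_summary(flat).courses["fv_fm"]
        assert course.time_of_min is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            simulate_stress_course(StressConfig(), "drought", seed=0)


class TestFameGenerator:
    def test_ground_truth_acu_matches_summary(self):
        """The stored ACU equals the analysis module's recomputation on
        every draw (cross-module oracle)."""
        for seed in range(20):
            syn = simulate_fame_profile(FameConfig(), seed=seed)
            s = saturation_summary(syn.profile)
            assert syn.truth["acu"] == pytest.approx(
                s.average_unsaturation, abs=1e-12)

    def test_totals_within_configured_range(self):
        for seed in range(10):
            syn = simulate_fame_profile(FameConfig(), seed=seed)
            assert 80.0 - 1e-9 <= syn.truth["total"] <= 100.0 + 1e-9
            assert syn.profile.total == pytest.approx(syn.truth["total"])

    def test_determinism(self):
        a = simulate_fame_profile(FameConfig(), seed=7)
        b = simulate_fame_profile(FameConfig(), seed=7)
        assert a.profile.fractions == b.profile.fractions

    def test_high_concentration_approaches_mixture_mean(self):
        cfg = FameConfig(concentration=5e6)
        syn = simulate_fame_profile(cfg, seed=1)
        s = saturation_summary(syn.profile)
        total = syn.profile.total
        assert s.sfa / total == pytest.approx(0.25, abs=0.01)
        assert s.pufa / total == pytest.approx(0.50, abs=0.01)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            FameConfig(class_weights=(0.6, 0.5, 0.2))
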