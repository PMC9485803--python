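"""Weighted residuals, subject-level fitting, manual-parameter grids and
regression statistics."""

import numpy as np
import pytest

from iigidyn.estimation import (DEFAULT_CVS, FitConfig, WeightingError,
                                fit_model, fit_statistics, grid_adjust_manual,
                                regression_statistics, weighted_residuals)
from iigidyn.model_core import Variant
from iigidyn.series import SubjectSeries
from iigidyn.synthetic_data import GenConfig, gen_subject
from iigidyn.validation import _fit_config_for


def _series(t, g, i, a):
    t = np.asarray(t, dtype=float)
    return SubjectSeries(t, np.asarray(g, float), np.asarray(i, float),
                         np.asarray(a, float))


class TestWeightedResiduals:
    def test_perfect_agreement_gives_zero(self):
        d = _series([0, 10], [5, 6], [60, 70], [9, 8])
        assert np.all(weighted_residuals(d, d) == 0.0)

    def test_single_point_arithmetic(self):
        d = _series([0], [5.0], [60.0], [9.0])
        s = _series([0], [4.9], [60.0], [9.0])
        r = weighted_residuals(d, s)
        assert r[0] == pytest.approx((5 - 4.9) / (0.02 * 5))  # = 1.0
        assert np.all(r[1:] == 0.0)

    def test_sse_decomposes_over_analytes(self):
        rng = np.random.default_rng(0)
        t = np.arange(5, dtype=float)
        d = _series(t, rng.uniform(4, 8, 5), rng.uniform(40, 80, 5),
                    rng.uniform(5, 12, 5))
        s = _series(t, rng.uniform(4, 8, 5), rng.uniform(40, 80, 5),
                    rng.uniform(5, 12, 5))
        r = weighted_residuals(d, s)
        per_analyte = sum(
            np.sum(weighted_residuals(d, s)[k * 5:(k + 1) * 5] ** 2)
            for k in range(3))
        assert np.sum(r ** 2) == pytest.approx(per_analyte)

    def test_unweighted_mode_returns_raw_differences(self):
        d = _series([0], [5.0], [60.0], [9.0])
        s = _series([0], [4.0], [50.0], [7.0])
        assert np.allclose(weighted_residuals(d, s, mode="unweighted"),
                           [1.0, 10.0, 2.0])

    def test_floor_bounds_detection_limit_weights(self):
        # glucagon at 0 would give infinite weight; the assay floor caps it
        d = _series([0], [5.0], [60.0], [0.0])
        s = _series([0], [5.0], [60.0], [0.5])
        r = weighted_residuals(d, s)
        assert r[2] == pytest.approx(-0.5 / (0.055 * 1.0))
        with pytest.raises(WeightingError):
            weighted_residuals(d, s, floors=(0.5, 5.0, 0.0))


class TestFitModel:
    def test_noiseless_self_consistency(self):
        """Refitting the generator's own noiseless output with true manual
        values recovers every free parameter to within 0.1%."""
        rng = np.random.default_rng(11)
        s = gen_subject("CS", rng, GenConfig(noise=False), seed=11)
        cfg = _fit_config_for(s, Variant.MODEL1_HILL, n_starts=1,
                              ftol=1e-14, xtol=1e-14)
        fit = fit_model(s.noiseless, s.schedule, cfg)
        truth = s.params.to_dict()
        for name in ("a1", "a2", "gamma1", "gamma2", "k1", "h"):
            assert fit.estimates[name] == pytest.approx(truth[name],
                                                        rel=1e-3), name
        assert fit.adj_r2 > 0.999999

    def test_noisy_estimates_statistically_consistent_with_truth(self):
        """At assay CVs every free estimate lies within 4 asymptotic
        standard errors of its true value (cohort-level accuracy is
        checked in the acceptance suite)."""
        rng = np.random.default_rng(5)
        s = gen_subject("CS", rng, GenConfig(noise=True), seed=5)
        fit = fit_model(s.noisy, s.schedule,
                        _fit_config_for(s, Variant.MODEL1_HILL, n_starts=1))
        truth = s.params.to_dict()
        assert fit.se_available
        for name in ("a1", "a2", "gamma1", "gamma2", "k1", "h"):
            z = abs(fit.estimates[name] - truth[name]) / fit.se[name]
            assert z < 4.0, (name, z)

    def test_nested_model_collapses_on_hill_truth(self):
        """A hysteresis fit of single-Hill data returns h1 ~ h2 within
        joint confidence bounds."""
        rng = np.random.default_rng(21)
        s = gen_subject("CS", rng, GenConfig(noise=True), seed=21)
        fit2 = fit_model(s.noisy, s.schedule,
                         _fit_config_for(s, Variant.MODEL2_HYSTERESIS,
                                         n_starts=1))
        h1, h2 = fit2.estimates["h1"], fit2.estimates["h2"]
        joint_se = np.hypot(fit2.se["h1"], fit2.se["h2"])
        assert abs(h1 - h2) < 3 * joint_se + 1e-6

    def test_objective_never_ends_above_start(self):
        rng = np.random.default_rng(3)
        s = gen_subject("CS", rng, GenConfig(noise=True), seed=3)
        fit = fit_model(s.noisy, s.schedule,
                        _fit_config_for(s, Variant.MODEL1_HILL, n_starts=1))
        costs = fit.cost_history
        assert costs.min() == pytest.approx(0.5 * fit.rss, rel=1e-6)
        # running best-so-far is monotone by construction; the final
        # accepted iterate is the best point seen
        assert costs[-1] <= costs[0]


class TestGridAdjustManual:
    def test_singleton_grid_equals_direct_fit(self):
        rng = np.random.default_rng(7)
        s = gen_subject("CS", rng, GenConfig(noise=True), seed=7)
        cfg = _fit_config_for(s, Variant.MODEL1_HILL, n_starts=1)
        manual, best = grid_adjust_manual(
            s.noisy, s.schedule,
            {k: [v] for k, v in cfg.manual.items()}, cfg)
        direct = fit_model(s.noisy, s.schedule, cfg)
        assert manual == cfg.manual
        assert best.rss == pytest.approx(direct.rss, rel=1e-9)

    def test_recovers_insulin_delay_on_grid(self):
        """Data generated with tau1 = 30 selects tau1 = 30 from
        {0, 15, 30, 45}, and the winner has the lowest SSE on the grid."""
        rng = np.random.default_rng(13)
        cfgen = GenConfig(noise=False)
        while True:
            s = gen_subject("T2D", rng, cfgen, seed=13)
            if s.params.tau1 > 0:  # force an exact grid value
                break
        p = s.params.with_updates(tau1=30.0)
        from iigidyn.model_core import SystemState, MGDL_PER_MM
        from iigidyn.synthetic_data import simulate_sampled
        init = SystemState(0.0, s.G0_mM * MGDL_PER_MM, s.I0_pM / 10, s.A0_pM)
        series, anchor, _ = simulate_sampled(p, s.schedule, init)
        cfg = FitConfig(variant=Variant.MODEL1_HILL, group="T2D", n_starts=1,
                        manual={"tau": p.tau, "tau1": 0.0, "tau2": p.tau2,
                                "k2": p.k2}, dt=0.25)
        grids = {"tau1": [0.0, 15.0, 30.0, 45.0]}
        manual, best = grid_adjust_manual(series, s.schedule, grids, cfg)
        assert manual["tau1"] == 30.0
        # argmin definition: winner beats every other grid point
        for other in (0.0, 15.0, 45.0):
            from dataclasses import replace
            alt = fit_model(series, s.schedule,
                            replace(cfg, manual={**manual, "tau1": other}))
            assert best.rss <= alt.rss + 1e-9


class TestRegressionStatistics:
    def _toy_fit(self, noise_sd=0.05, seed=0, n=40):
        """2-parameter exponential decay fit via the package statistics."""
        from scipy.optimize import least_squares
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 5, n)
        y = 3.0 * np.exp(-0.8 * t) + noise_sd * rng.standard_normal(n)

        def resid(x):
            return y - x[0] * np.exp(-x[1] * t)

        sol = least_squares(resid, [1.0, 1.0])
        return t, y, sol

    def test_matches_lmfit_reference(self):
        import lmfit
        t, y, sol = self._toy_fit()
        rss, se, adj_r2, aicc_v, ok = regression_statistics(
            sol.jac, sol.fun, y, len(y), 2)
        model = lmfit.Model(lambda x, A, b: A * np.exp(-b * x))
        ref = model.fit(y, x=t, A=1.0, b=1.0)
        assert ok
        assert se[0] == pytest.approx(ref.params["A"].stderr, rel=1e-3)
        assert se[1] == pytest.approx(ref.params["b"].stderr, rel=1e-3)
        assert rss == pytest.approx(ref.chisqr, rel=1e-8)

    def test_perfect_fit_gives_adjusted_r2_of_one(self):
        t, y, sol = self._toy_fit(noise_sd=0.0)
        rss, se, adj_r2, aicc_v, ok = regression_statistics(
            sol.jac, sol.fun, y, len(y), 2)
        assert adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_null_parameter_pvalue_calibration(self):
        """A parameter whose true value is 0 should rarely be declared
        significant: p > 0.05 in >= ~90% of replicates."""
        from scipy import stats as sps
        from scipy.optimize import least_squares
        n = 60
        t = np.linspace(0, 5, n)
        hits = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            y = 3.0 * np.exp(-0.8 * t) + 0.05 * rng.standard_normal(n)

            def resid(x):
                return y - (x[0] * np.exp(-x[1] * t) + x[2] * t)

            sol = least_squares(resid, [3.0, 0.8, 0.0])
            rss, se, *_ = regression_statistics(sol.jac, sol.fun, y, n, 3)
            pval = 2 * sps.t.sf(abs(sol.x[2] / se[2]), n - 3)
            hits += pval > 0.05
        assert hits / reps >= 0.85

    def test_fit_statistics_accessor(self):
        rng = np.random.default_rng(9)
        s = gen_subject("CS", rng, GenConfig(noise=True), seed=9)
        fit = fit_model(s.noisy, s.schedule,
                        _fit_config_for(s, Variant.MODEL1_HILL, n_starts=1))
        adj_r2, se, pvals, aicc_v = fit_statistics(fit)
        assert adj_r2 <= 1.0
        assert all(v >= 0 for v in se.values())
        assert np.isfinite(aicc_v)
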