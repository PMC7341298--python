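"""Per-bird nonlinear fitting: recovery, goodness of fit, correlations."""

import numpy as np
import pytest

import flockfit as ff
from flockfit.fitting import FALLBACK_INIT, GompertzModel

TRUE = ff.G1Params(bwa=2500.0, b=3.4, k=0.015)
SCHED = np.arange(0.0, 225.0, 14.0)


def make_trajectory(params=TRUE, noise_cv=0.0, seed=0, breed="BS", sex="F"):
    rng = np.random.default_rng(seed)
    w = np.asarray(ff.predict_g1(params, SCHED))
    if noise_cv:
        w = w * (1 + noise_cv * rng.standard_normal(SCHED.size))
    return ff.Trajectory("bird", breed, sex, SCHED, w)


class TestFit:
    def test_noiseless_recovery_both_forms(self):
        tr = make_trajectory()
        r1 = ff.fit_trajectory(tr, model="g1")
        assert r1.converged
        assert r1.params.bwa == pytest.approx(TRUE.bwa, rel=1e-6)
        assert r1.params.b == pytest.approx(TRUE.b, rel=1e-6)
        assert r1.params.k == pytest.approx(TRUE.k, rel=1e-6)
        r2 = ff.fit_trajectory(tr, model="g2")
        truth2 = ff.convert_g1_to_g2(TRUE)
        assert r2.params.bwa == pytest.approx(truth2.bwa, rel=1e-6)
        assert r2.params.mu == pytest.approx(truth2.mu, rel=1e-6)
        assert r2.params.lam == pytest.approx(truth2.lam, rel=1e-4)

    def test_three_points_interpolated_exactly(self):
        # 3 observations determine the 3 parameters: the fit interpolates
        t = np.array([10.0, 80.0, 200.0])
        w = np.asarray(ff.predict_g1(TRUE, t))
        r = GompertzModel(t, w, "g1").fit()
        assert r.rss < 1e-12 * float(np.mean(w) ** 2)

    def test_constant_trajectory_flagged_not_silent(self):
        tr = ff.Trajectory("x", "BS", "F", SCHED, np.full(SCHED.size, 40.0))
        r = ff.fit_trajectory(tr, model="g1")
        assert not r.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ff.fit_trajectory(
                ff.Trajectory("x", "BS", "F", SCHED[:4], np.array([40, 100, 200, 400.0]))
            )

    def test_refit_from_own_estimates_is_fixed_point(self):
        tr = make_trajectory(noise_cv=0.05, seed=3)
        m = GompertzModel.from_trajectory(tr, "g1")
        r1 = m.fit()
        r2 = m.fit(init=r1.params)
        assert r2.params.bwa == pytest.approx(r1.params.bwa, rel=1e-7)
        assert r2.params.k == pytest.approx(r1.params.k, rel=1e-6)

    def test_fitted_weights_monotone(self):
        r = ff.fit_trajectory(make_trajectory(noise_cv=0.05, seed=1))
        assert np.all(np.diff(r.fitted_weights) > 0)


class TestTrajectoryValidation:
    def test_duplicate_times_rejected(self):
        t = SCHED.copy(); t[3] = t[2]
        with pytest.raises(ValueError, match="strictly increasing"):
            ff.Trajectory("x", "BS", "F", t, np.linspace(40, 2000, t.size))

    def test_nonpositive_weights_rejected(self):
        w = np.linspace(40, 2000, SCHED.size); w[0] = -5
        with pytest.raises(ValueError, match="positive"):
            ff.Trajectory("x", "BS", "F", SCHED, w)


class TestDefaultInit:
    def test_init_near_truth_and_converges(self):
        tr = make_trajectory(noise_cv=0.03, seed=7)
        m = GompertzModel.from_trajectory(tr, "g1")
        init = m.default_init()
        assert init.bwa == pytest.approx(TRUE.bwa, rel=0.5)
        assert init.b == pytest.approx(TRUE.b, rel=0.5)
        assert init.k == pytest.approx(TRUE.k, rel=0.5)
        assert m.fit(init=init).converged

    def test_asymptote_guess_is_inflated_max(self):
        w = np.linspace(40, 2000, SCHED.size)
        init = GompertzModel(SCHED, w, "g1").default_init()
        assert init.bwa == pytest.approx(2400.0)

    def test_degenerate_input_falls_back(self):
        w = np.full(SCHED.size, 40.0)
        init = GompertzModel(SCHED, w, "g1").default_init()
        assert init == FALLBACK_INIT


class TestGoodness:
    def test_perfect_fit(self):
        r = ff.fit_trajectory(make_trajectory())
        assert r.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert r.aic == float("-inf") or r.aic < -300  # rss at machine precision

    def test_r2_adj_undefined_with_minimal_points(self):
        t = np.array([0.0, 50.0, 120.0, 220.0])
        w = np.asarray(ff.predict_g1(TRUE, t)) * 1.01
        r = GompertzModel(t, w, "g1").fit()
        with pytest.raises(ValueError, match="undefined"):
            ff.goodness(r)

    def test_goodness_values_match_formulas(self):
        r = ff.fit_trajectory(make_trajectory(noise_cv=0.05, seed=5))
        g = ff.goodness(r)
        n, p = r.n_obs, r.n_params
        r2 = 1 - r.rss / r.tss
        assert g["r2_adj"] == pytest.approx(1 - (1 - r2) * (n - 1) / (n - p - 1))
        assert g["aic"] == pytest.approx(n * np.log(r.rss / n) + 2 * (p + 1))


class TestWeeklyCorrelation:
    def test_identical_matrices_give_unit_correlation(self):
        a = np.random.default_rng(0).normal(1000, 100, (30, 5))
        r = ff.weekly_correlation(a, a)
        assert np.allclose(r, 1.0)

    def test_zero_variance_column_is_undefined_marker(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1000, 100, (30, 3))
        a[:, 0] = 39.0  # identical hatch weights
        f = rng.normal(1000, 100, (30, 3))
        r = ff.weekly_correlation(a, f)
        assert np.isnan(r[0]) and np.all(np.isfinite(r[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ff.weekly_correlation(np.ones((3, 2)), np.ones((2, 3)))

    def test_fitted_vs_actual_increases_with_age(self, default_dataset, default_g1_fits):
        results, _ = default_g1_fits
        actual = np.vstack([tr.weights for tr in default_dataset.trajectories])
        fitted = np.vstack([r.fitted_weights for r in results])
        r = ff.weekly_correlation(actual, fitted)
        assert np.all(r[1:] > 0.9)  # from 2 w of age on
        assert r[8] > r[1]


class TestParameterCorrelations:
    def test_bwip_bwa_correlation_is_unity(self, default_g1_fits):
        results, _ = default_g1_fits
        corr = ff.parameter_correlations(results)
        assert corr.loc["bwip", "bwa"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_growth_rate_negatively_correlated_with_inflection_age(self):
        # independent BWa and k; Tip = ln(b)/k forces corr(k, Tip) < 0
        rng = np.random.default_rng(4)
        results = []
        for _ in range(60):
            p = ff.G1Params(
                rng.normal(2500, 200), rng.normal(3.4, 0.2), rng.normal(0.015, 0.0015)
            )
            w = np.asarray(ff.predict_g1(p, SCHED)) * (
                1 + 0.02 * rng.standard_normal(SCHED.size)
            )
            results.append(GompertzModel(SCHED, w, "g1").fit())
        corr = ff.parameter_correlations(results)
        assert corr.loc["k", "tip"] < -0.3

    def test_too_few_fits_rejected(self):
        r = ff.fit_trajectory(make_trajectory())
        with pytest.raises(ValueError, match="at least 3"):
            ff.parameter_correlations([r, r])


def test_group_mean_recovery_under_noise(default_dataset, default_g1_fits):
    """5% multiplicative noise leaves group-mean asymptotes within 5% of truth."""
    _, table = default_g1_fits
    truth = default_dataset.truth
    for (breed, sex), sub in table.groupby(["breed", "sex"]):
        true_mean = truth.query("breed == @breed and sex == @sex")["bwa"].mean()
        assert sub["bwa"].mean() == pytest.approx(true_mean, rel=0.05)
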