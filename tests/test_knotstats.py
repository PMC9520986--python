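"""Knotting-curve statistics: P0 estimation, exponential and mu fits, Eq-8-style estimator."""

import math

import numpy as np
import pandas as pd
import pytest

from fractalknots import beta_model as bm
from fractalknots import knotstats as ks


class TestEstimateP0:
    def test_point_estimate_and_interval(self):
        p, (lo, hi) = ks.estimate_p0(1000, 900)
        assert p == 0.9
        assert 0.87 < lo < hi < 0.92

    def test_boundary_all_unknots(self):
        p, (lo, hi) = ks.estimate_p0(50, 50)
        assert p == 1.0
        assert hi == 1.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            ks.estimate_p0(0, 0)

    def test_wilson_coverage(self):
        # brute-force coverage simulation at p = 0.3, n = 200
        p_true, n = 0.3, 200
        rng = np.random.default_rng(17)
        intervals = {k: ks.wilson_interval(k, n) for k in range(n + 1)}
        draws = rng.binomial(n, p_true, size=10000)
        covered = np.array(
            [intervals[k][0] <= p_true <= intervals[k][1] for k in draws]
        )
        assert 0.93 < covered.mean() < 0.97


class TestFitExponential:
    def test_noiseless_curve_recovers_n0_exactly(self):
        N = np.arange(100, 601, 100)
        trials = 10**9
        unknot = np.round(trials * np.exp(-N / 250.0)).astype(int)
        curve = ks.KnottingCurve.from_counts(N, trials, unknot, d_f=2.0)
        fit = ks.fit_exponential(curve)
        assert fit.N0 == pytest.approx(250.0, rel=1e-3)
        assert fit.mu == pytest.approx(math.log(fit.N0), rel=1e-14)

    def test_parameter_recovery_over_replicates(self):
        # known N0, binomial noise: recovery within 2 SE in >= 93/100 runs
        rng = np.random.default_rng(23)
        N = np.arange(100, 601, 100)
        hits = 0
        for _ in range(100):
            curve = ks.generate_bernoulli_curve(250.0, N, 5000, rng)
            fit = ks.fit_exponential(curve)
            se_n0 = fit.N0**2 * fit.slope_stderr
            if abs(fit.N0 - 250.0) < 2 * se_n0:
                hits += 1
        assert hits >= 93

    def test_increasing_curve_is_degenerate(self):
        N = np.array([100, 200, 300, 400])
        unknot = np.array([100, 200, 400, 800])
        curve = ks.KnottingCurve.from_counts(N, 1000, unknot, d_f=2.0)
        with pytest.raises(ks.FitDegenerate):
            ks.fit_exponential(curve)

    def test_too_few_usable_points(self):
        curve = ks.KnottingCurve.from_counts(
            [10, 20, 30], 100, [100, 100, 0], d_f=2.0
        )
        with pytest.raises(ks.FitDegenerate):
            ks.fit_exponential(curve)


class TestMuCurve:
    def _fit(self, d_f, n0, err=0.05):
        return ks.ExponentialFit(
            N0=n0,
            mu=math.log(n0),
            mu_stderr=err,
            prefactor=1.0,
            slope=-1 / n0,
            slope_stderr=err / n0,
            chi2_reduced=1.0,
            window=(0, 0),
            n_points=5,
            d_f=d_f,
        )

    def test_mu_is_log_n0(self):
        fits = [self._fit(2.0, math.e**3), self._fit(3.0, 50), self._fit(4.0, 40), self._fit(5.0, 35)]
        curve = ks.build_mu_curve(fits)
        assert curve.data.loc[curve.data.d_f == 2.0, "mu"].item() == pytest.approx(3.0)
        assert list(curve.data.d_f) == sorted(curve.data.d_f)

    def test_duplicate_df_rejected(self):
        fits = [self._fit(2.0, 100)] * 4
        with pytest.raises(ValueError):
            ks.build_mu_curve(fits)

    def test_doubling_trials_shrinks_mu_stderr_sqrt2(self):
        # binomial-variance oracle: same noiseless counts, doubled statistics
        N = np.arange(100, 601, 100)
        mus = []
        for trials in (10000, 20000):
            unknot = np.round(trials * np.exp(-N / 250.0)).astype(int)
            curve = ks.KnottingCurve.from_counts(N, trials, unknot, d_f=2.0)
            mus.append(ks.fit_exponential(curve).mu_stderr)
        assert mus[0] / mus[1] == pytest.approx(math.sqrt(2), rel=0.02)


class TestFitMu:
    GRID = np.linspace(1.2, 5.0, 24)

    def _curve(self, mu, err=0.02):
        return ks.MuCurve(
            pd.DataFrame({"d_f": self.GRID, "mu": mu, "mu_stderr": err})
        )

    def test_noiseless_double_exponential_recovery(self):
        c_true = (16.9, -1.138, 3.703)
        mu = c_true[0] * np.exp(c_true[1] * self.GRID) + c_true[2]
        fit = ks.fit_mu(self._curve(mu), "double_exponential")
        for got, want in zip((fit.c1, fit.c2, fit.c3), c_true):
            assert got == pytest.approx(want, rel=1e-6)

    def test_logarithmic_fit_leaves_structured_residuals(self):
        mu = 16.9 * np.exp(-1.138 * self.GRID) + 3.703
        log_fit = ks.fit_mu(self._curve(mu), "logarithmic")
        assert log_fit.runs_pvalue < 0.05
        de_fit = ks.fit_mu(self._curve(mu), "double_exponential")
        assert de_fit.aicc < log_fit.aicc

    def test_unknown_model_rejected(self):
        mu = np.linspace(8, 4, 24)
        with pytest.raises(ValueError):
            ks.fit_mu(self._curve(mu), "power_law")


class TestDerivativeEstimator:
    def test_null_when_constraint_disabled(self, rng):
        sp = bm.build_spectrum(100, 3.0, 3)
        pos = bm.sample_rings(sp, 4000, rng)
        est, err = ks.derivative_estimator(pos, None, sp, 90.0, constrained=False)
        assert abs(est) < 4 * err

    def test_rejects_unmixed_samples(self, rng):
        sp = bm.build_spectrum(60, 3.0, 3)
        pos = bm.sample_rings(sp, 100, rng)
        with pytest.raises(ValueError):
            ks.derivative_estimator(pos, np.ones(100, dtype=bool), sp, 90.0)
        with pytest.raises(ValueError):
            ks.derivative_estimator(pos, np.zeros(100, dtype=bool), sp, 90.0)


class TestBernoulliCurves:
    def test_large_trials_limit(self, rng):
        N = np.arange(50, 301, 50)
        curve = ks.generate_bernoulli_curve(100.0, N, 10**6, rng)
        np.testing.assert_allclose(
            curve.data.p0, np.exp(-N / 100.0), rtol=0.02
        )

    def test_single_trial_per_point_is_valid(self, rng):
        curve = ks.generate_bernoulli_curve(100.0, [50, 100], 1, rng)
        assert ((curve.data.ci_hi - curve.data.ci_lo) > 0.5).all()
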