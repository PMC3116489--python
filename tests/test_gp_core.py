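"""Unit and property tests for the SE-kernel GP core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from gpderank import (
    ConditioningError,
    InvalidHyperparameterError,
    SEHyperparams,
    SNRParams,
    TimeCourseProfile,
    log_marginal_likelihood,
    lml_gradient,
    optimize_hyperparams,
    predict,
    se_kernel,
)
from gpderank.gp_core import _se_cross

from conftest import random_hyperparams, random_profile


def mvn_lml_oracle(t, y, hyp):
    """Dense multivariate-normal log-density, independent of the GP code path."""
    t = np.asarray(t, float)
    d2 = (t[:, None] - t[None, :]) ** 2
    if math.isinf(hyp.lengthscale_sq):
        Kf = np.full(d2.shape, hyp.signal_variance)
    else:
        Kf = hyp.signal_variance * np.exp(-d2 / (2 * hyp.lengthscale_sq))
    K = Kf + hyp.noise_variance * np.eye(len(t))
    return float(multivariate_normal(np.zeros(len(t)), K, allow_singular=True).logpdf(np.asarray(y)))


class TestSEKernel:
    def test_diagonal_adds_noise_on_self_covariance(self):
        hyp = SEHyperparams(1.0, 1.0, 0.5)
        K = se_kernel([3.0], [3.0], hyp)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(1.5)

    def test_cross_covariance_has_no_noise_term(self):
        hyp = SEHyperparams(1.0, 1.0, 0.5)
        K = se_kernel([3.0], [3.0, 4.0], hyp)
        assert K[0, 0] == pytest.approx(1.0)

    def test_stationary_decay_to_zero(self):
        hyp = SEHyperparams(1.0, 1.0, 0.0)
        K = se_kernel([0.0], [100.0], hyp)
        assert K[0, 0] < 1e-300

    def test_scalar_value_matches_closed_form(self):
        # sigma_f^2=2, l^2=4, d=2 -> 2*exp(-4/(2*4)) = 2*exp(-1/2)
        hyp = SEHyperparams(4.0, 2.0, 0.0)
        K = se_kernel([0.0], [2.0], hyp)
        assert K[0, 0] == pytest.approx(2.0 * math.exp(-0.5), rel=1e-14)

    def test_infinite_lengthscale_is_constant_kernel(self):
        hyp = SEHyperparams(math.inf, 2.0, 0.0)
        K = se_kernel(np.array([0.0, 5.0, 100.0]), np.array([1.0, 2.0]), hyp)
        assert np.all(K == 2.0)

    def test_invalid_hyperparameters_raise(self):
        with pytest.raises(InvalidHyperparameterError):
            SEHyperparams(0.0, 1.0, 1.0)
        with pytest.raises(InvalidHyperparameterError):
            SEHyperparams(1.0, -1.0, 1.0)
        with pytest.raises(InvalidHyperparameterError):
            SEHyperparams(1.0, 0.0, 0.0)
        with pytest.raises(InvalidHyperparameterError):
            SEHyperparams(float("nan"), 1.0, 1.0)

    @given(st.integers(0, 1000))
    def test_self_covariance_symmetric_psd(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 10, size=rng.integers(2, 10))
        hyp = random_hyperparams(rng)
        K = se_kernel(t, t, hyp)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-9


class TestLogMarginalLikelihood:
    def test_pure_noise_standard_normal_at_origin(self):
        # y=0 so centring is a no-op; sigma_f^2=0, sigma_n^2=1 -> -(N/2) log 2pi
        n = 5
        p = TimeCourseProfile("z", np.arange(n), np.zeros(n))
        hyp = SEHyperparams(1.0, 0.0, 1.0)
        assert log_marginal_likelihood(p, hyp) == pytest.approx(-n / 2 * math.log(2 * math.pi))

    def test_matches_dense_mvn_oracle_small_instance(self):
        p = TimeCourseProfile("p", [0.0, 1.0, 2.0], [1.0, 0.0, -1.0])
        hyp = SEHyperparams(1.0, 1.0, 0.1)
        assert log_marginal_likelihood(p, hyp) == pytest.approx(
            mvn_lml_oracle([0, 1, 2], [1, 0, -1], hyp), abs=1e-8
        )

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            p = random_profile(rng, int(rng.integers(3, 13)))
            hyp = random_hyperparams(rng)
            t, y, _ = p.centred()
            assert log_marginal_likelihood(p, hyp) == pytest.approx(
                mvn_lml_oracle(t, y, hyp), abs=1e-8
            )

    def test_translation_invariance(self, rng):
        p = random_profile(rng, 8)
        hyp = random_hyperparams(rng)
        shifted = TimeCourseProfile(p.probe_id, p.times + 137.5, p.values)
        assert log_marginal_likelihood(shifted, hyp) == pytest.approx(
            log_marginal_likelihood(p, hyp), rel=1e-10
        )

    def test_matches_sklearn_gp_cross_check(self):
        # independent route: sklearn's GP marginal likelihood at fixed kernel
        sk = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 10, 9))
        y = rng.normal(0, 1, 9)
        y = y - y.mean()
        hyp = SEHyperparams(4.0, 1.3, 0.4)
        kern = ConstantKernel(1.3, "fixed") * RBF(2.0, "fixed") + WhiteKernel(0.4, "fixed")
        gp = sk.GaussianProcessRegressor(kernel=kern, optimizer=None, alpha=0.0)
        gp.fit(t.reshape(-1, 1), y)
        p = TimeCourseProfile("p", t, y)
        assert log_marginal_likelihood(p, hyp) == pytest.approx(
            gp.log_marginal_likelihood_value_, abs=1e-7
        )

    def test_missing_values_are_dropped(self, rng):
        t = np.arange(6.0)
        y = rng.normal(size=6)
        mask = np.array([False, True, False, False, True, False])
        p = TimeCourseProfile("m", t, y, mask)
        q = TimeCourseProfile("m", t[~mask], y[~mask])
        hyp = random_hyperparams(rng)
        assert log_marginal_likelihood(p, hyp) == pytest.approx(log_marginal_likelihood(q, hyp))

    def test_rank_deficient_self_covariance_is_rescued_by_jitter(self):
        # identical times, zero noise: K_y is rank-1 but jitter escalation
        # keeps the factorization finite
        t = np.zeros(6)
        y = np.array([1.0, -1.0, 2.0, -2.0, 0.5, 1.5])
        p = TimeCourseProfile("rank1", t, y)
        assert math.isfinite(log_marginal_likelihood(p, SEHyperparams(1.0, 1.0, 0.0)))

    def test_conditioning_error_names_profile(self):
        # an indefinite matrix stays non-PD past the maximum admissible jitter
        from gpderank.gp_core import _chol_with_jitter

        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ConditioningError, match="bad_probe"):
            _chol_with_jitter(bad, "bad_probe")


class TestGradient:
    @staticmethod
    def fd_gradient(p, hyp, h=1e-5):
        """Central finite differences over the log-hyperparameters."""
        logs = np.log([hyp.lengthscale_sq, hyp.signal_variance, hyp.noise_variance])
        g = np.zeros(3)
        for i in range(3):
            up, dn = logs.copy(), logs.copy()
            up[i] += h
            dn[i] -= h
            g[i] = (
                log_marginal_likelihood(p, SEHyperparams(*np.exp(up)))
                - log_marginal_likelihood(p, SEHyperparams(*np.exp(dn)))
            ) / (2 * h)
        return g

    def test_matches_finite_differences_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            p = random_profile(rng, 6)
            hyp = random_hyperparams(rng)
            g = lml_gradient(p, hyp)
            fd = self.fd_gradient(p, hyp)
            assert np.allclose(g, fd, rtol=1e-5, atol=1e-7)

    def test_zero_at_interior_maximum(self, rng):
        # optimize first, then the analytic gradient must vanish
        p = random_profile(rng, 12)
        init = SNRParams(5.0, 1.0, p.ml_variance())
        fit = optimize_hyperparams(p, init, constrain_variance_sum=False)
        g = lml_gradient(p, fit.hyperparams)
        assert np.abs(g).max() < 1e-3

    def test_zero_signal_boundary_component_excluded(self):
        p = TimeCourseProfile("p", [0.0, 1.0, 2.0], [0.3, -0.1, 0.2])
        g = lml_gradient(p, SEHyperparams(1.0, 0.0, 1.0))
        assert g[0] == 0.0 and g[1] == 0.0
        assert math.isfinite(g[2])


class TestOptimize:
    def test_ascent_from_any_init(self, rng):
        p = random_profile(rng, 10)
        init = SNRParams(20.0, 1e3, p.ml_variance())
        lml0 = log_marginal_likelihood(p, init.to_hyperparams())
        fit = optimize_hyperparams(p, init, constrain_variance_sum=True)
        assert fit.lml >= lml0 - 1e-6

    def test_constrained_fit_preserves_variance_sum(self, rng):
        p = random_profile(rng, 12)
        v = p.ml_variance()
        fit = optimize_hyperparams(p, SNRParams(5.0, 10.0, v), constrain_variance_sum=True)
        assert fit.hyperparams.signal_variance + fit.hyperparams.noise_variance == pytest.approx(v)

    def test_pure_noise_profile_lands_near_null_model(self):
        from gpderank import null_lml

        rng = np.random.default_rng(5)
        t = np.repeat(np.arange(11.0), 4)
        p = TimeCourseProfile("noise", t, rng.normal(0, 1, len(t)))
        fit = optimize_hyperparams(p, SNRParams(20.0, 1e3, p.ml_variance()), constrain_variance_sum=True)
        snr = fit.hyperparams.signal_variance / fit.hyperparams.noise_variance
        assert fit.lml <= null_lml(p) + 2.0
        assert snr < 1.0

    def test_parameter_recovery_on_self_simulated_profile(self):
        # paired-point design over a long span: best identifiability per the
        # Fisher-information analysis in the methods note
        true = SEHyperparams(8.0, 0.55, 0.18)
        tu = np.sort(np.concatenate([np.linspace(0, 300, 100), np.linspace(0, 300, 100) + 0.75]))
        rng = np.random.default_rng(0)
        f = rng.multivariate_normal(np.zeros(len(tu)), _se_cross(tu, tu, true), method="eigh")
        y = f + rng.normal(0, math.sqrt(true.noise_variance), len(tu))
        p = TimeCourseProfile("rec", tu, y)
        fits = [
            optimize_hyperparams(p, SNRParams(l2, 1.0, p.ml_variance()), constrain_variance_sum=False)
            for l2 in (5.0, 20.0, 80.0)
        ]
        h = max(fits, key=lambda f: f.lml).hyperparams
        assert h.lengthscale_sq == pytest.approx(true.lengthscale_sq, rel=0.25)
        assert h.signal_variance == pytest.approx(true.signal_variance, rel=0.25)
        assert h.noise_variance == pytest.approx(true.noise_variance, rel=0.25)

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        p = random_profile(rng, 12)
        fit = optimize_hyperparams(p, SNRParams(20.0, 1e3, p.ml_variance()), max_iter=1)
        assert isinstance(fit.converged, bool)  # no exception; flag carries the outcome


class TestPredict:
    def test_noiseless_interpolation_at_training_points(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.5, -0.2, 0.9, 0.1])
        p = TimeCourseProfile("p", t, y)
        hyp = SEHyperparams(2.0, 1.0, 1e-10)
        pred = predict(p, hyp, t)
        assert np.allclose(pred.mean, y, atol=1e-6)
        assert np.all(pred.variance < 1e-6)

    def test_reversion_to_prior_far_from_data(self):
        t = np.array([0.0, 1.0, 2.0])
        p = TimeCourseProfile("p", t, [5.0, 6.0, 7.0])
        hyp = SEHyperparams(1.0, 1.3, 0.2)
        pred = predict(p, hyp, [1000.0], include_noise=False)
        assert pred.mean[0] == pytest.approx(6.0, abs=1e-8)  # profile mean
        assert pred.variance[0] == pytest.approx(1.3, rel=1e-8)
        noisy = predict(p, hyp, [1000.0], include_noise=True)
        assert noisy.variance[0] == pytest.approx(1.5, rel=1e-8)

    def test_two_point_closed_form(self):
        # hand-expanded 2x2 inverse: K=[[a,b],[b,a]], a=sf2+sn2, b=sf2*exp(-1/(2 l2))
        l2, sf2, sn2 = 2.0, 1.5, 0.3
        y = np.array([1.0, -1.0])  # zero mean, centring is a no-op
        t = np.array([0.0, 1.0])
        a = sf2 + sn2
        b = sf2 * math.exp(-1.0 / (2 * l2))
        xq = 0.25
        k1 = sf2 * math.exp(-(xq - 0.0) ** 2 / (2 * l2))
        k2 = sf2 * math.exp(-(xq - 1.0) ** 2 / (2 * l2))
        det = a * a - b * b
        alpha = np.array([(a * 1.0 - b * -1.0) / det, (-b * 1.0 + a * -1.0) / det])
        mean_cf = k1 * alpha[0] + k2 * alpha[1]
        kK = np.array([(a * k1 - b * k2) / det, (-b * k1 + a * k2) / det])
        var_cf = sf2 - (k1 * kK[0] + k2 * kK[1])
        pred = predict(TimeCourseProfile("p", t, y), SEHyperparams(l2, sf2, sn2), [xq])
        assert pred.mean[0] == pytest.approx(mean_cf, rel=1e-10)
        assert pred.variance[0] == pytest.approx(var_cf, rel=1e-10)

    def test_translation_invariance_of_predictions(self, rng):
        p = random_profile(rng, 7)
        hyp = random_hyperparams(rng)
        q = TimeCourseProfile(p.probe_id, p.times + 42.0, p.values)
        xq = np.linspace(0, 10, 5)
        a = predict(p, hyp, xq)
        b = predict(q, hyp, xq + 42.0)
        assert np.allclose(a.mean, b.mean, atol=1e-9)
        assert np.allclose(a.variance, b.variance, atol=1e-9)


class TestSNRParams:
    def test_bijection_with_hyperparams(self):
        s = SNRParams(lengthscale_sq=3.0, snr=4.0, total_variance=2.5)
        h = s.to_hyperparams()
        assert h.signal_variance == pytest.approx(2.5 * 4 / 5)
        assert h.noise_variance == pytest.approx(2.5 / 5)
        back = SNRParams.from_hyperparams(h)
        assert back.snr == pytest.approx(4.0)
        assert back.total_variance == pytest.approx(2.5)

    def test_complexity_does_not_beat_null_on_white_noise(self):
        # fitness/complexity trade-off of the marginal likelihood: on pure
        # noise an expressive configuration gains at most ~chi2_2/2 nats
        from gpderank import null_lml

        rng = np.random.default_rng(17)
        t = np.repeat(np.arange(11.0), 4)
        worst = -np.inf
        for i in range(20):
            p = TimeCourseProfile(f"n{i}", t, rng.normal(0, 1, len(t)))
            fit = optimize_hyperparams(p, SNRParams(20.0, 1e3, p.ml_variance()))
            worst = max(worst, fit.lml - null_lml(p))
        assert worst < 7.0  # 99.9th pct of chi2(2)/2 is ~6.9
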