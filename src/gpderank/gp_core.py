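"""Squared-exponential Gaussian-process regression for expression time courses.

One gene expression profile is modelled as noisy observations of a latent
smooth function of time,

    y(t) = f(t) + eps,   f ~ GP(0, k),   eps ~ N(0, sigma_n^2) i.i.d.,

with the noisy univariate squared-exponential (SE) covariance

    k(t_i, t_j) = sigma_f^2 * exp(-(t_i - t_j)^2 / (2 l^2)) + sigma_n^2 * delta_ij.

``l^2`` is the squared characteristic lengthscale (time-units squared; large
values encode near-constant functions, ``l^2 = +inf`` is the exact constant
limit), ``sigma_f^2`` the signal variance (vertical scale of function
variation) and ``sigma_n^2`` the observation-noise variance.  Biological
replicates enter as repeated time coordinates; the noise term absorbs
replicate scatter.  Missing observations are dropped before fitting.

The module provides the kernel, the log-marginal likelihood (LML) and its
analytic gradient in log-hyperparameter space, gradient-based hyperparameter
optimisation (optionally in the two-dimensional (l^2, SNR) parameterisation
with sigma_f^2 + sigma_n^2 pinned to the observed profile variance), and the
GP predictive distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "TimeCourseProfile",
    "SEHyperparams",
    "SNRParams",
    "GPFit",
    "PredictiveDistribution",
    "InvalidHyperparameterError",
    "ConditioningError",
    "se_kernel",
    "log_marginal_likelihood",
    "lml_gradient",
    "optimize_hyperparams",
    "predict",
]

# Jitter escalation: start at 1e-8 * mean(diag) and multiply by 10 until the
# Cholesky succeeds or the relative jitter exceeds 1e-2.
_JITTER_START = 1e-8
_JITTER_MAX = 1e-2
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


class InvalidHyperparameterError(ValueError):
    """Raised when kernel hyperparameters violate their constraints."""


class ConditioningError(RuntimeError):
    """Raised when a covariance matrix stays non-positive-definite after
    the maximum admissible jitter."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SEHyperparams:
    """Hyperparameters of the noisy univariate SE kernel.

    Parameters
    ----------
    lengthscale_sq
        Squared characteristic lengthscale ``l^2`` (time-units^2).  May be
        ``math.inf`` for the constant-function limit.
    signal_variance
        Signal variance ``sigma_f^2`` (expression-units^2).
    noise_variance
        Observation-noise variance ``sigma_n^2`` (expression-units^2).
    """

    lengthscale_sq: float
    signal_variance: float
    noise_variance: float

    def __post_init__(self) -> None:
        l2, sf2, sn2 = self.lengthscale_sq, self.signal_variance, self.noise_variance
        if math.isnan(l2) or math.isnan(sf2) or math.isnan(sn2):
            raise InvalidHyperparameterError("hyperparameters must not be NaN")
        if not (l2 > 0):  # +inf allowed
            raise InvalidHyperparameterError(f"lengthscale_sq must be > 0, got {l2!r}")
        if not math.isfinite(sf2) or sf2 < 0:
            raise InvalidHyperparameterError(f"signal_variance must be finite and >= 0, got {sf2!r}")
        if not math.isfinite(sn2) or sn2 < 0:
            raise InvalidHyperparameterError(f"noise_variance must be finite and >= 0, got {sn2!r}")
        if sf2 + sn2 <= 0:
            raise InvalidHyperparameterError("signal_variance + noise_variance must be > 0")


@dataclass(frozen=True)
class SNRParams:
    """Two-dimensional reparameterisation (l^2, SNR) of the SE kernel.

    With the constraint ``sigma_f^2 + sigma_n^2 = total_variance`` the
    three-dimensional hyperparameter search reduces to two dimensions:
    ``sigma_f^2 = total_variance * snr / (1 + snr)`` and
    ``sigma_n^2 = total_variance / (1 + snr)``.
    """

    lengthscale_sq: float
    snr: float
    total_variance: float

    def __post_init__(self) -> None:
        if not (self.lengthscale_sq > 0):
            raise InvalidHyperparameterError("lengthscale_sq must be > 0")
        if not (self.snr >= 0):
            raise InvalidHyperparameterError("snr must be >= 0")
        if not (self.total_variance > 0):
            raise InvalidHyperparameterError("total_variance must be > 0")

    def to_hyperparams(self) -> SEHyperparams:
        v, s = self.total_variance, self.snr
        if math.isinf(s):
            return SEHyperparams(self.lengthscale_sq, v, 0.0)
        return SEHyperparams(self.lengthscale_sq, v * s / (1.0 + s), v / (1.0 + s))

    @classmethod
    def from_hyperparams(cls, hyp: SEHyperparams) -> "SNRParams":
        v = hyp.signal_variance + hyp.noise_variance
        snr = math.inf if hyp.noise_variance == 0 else hyp.signal_variance / hyp.noise_variance
        return cls(hyp.lengthscale_sq, snr, v)


@dataclass
class TimeCourseProfile:
    """Observations of one gene: times, values and a missing-value mask.

    Repeated time coordinates encode replicates.  ``missing_mask[i]`` is True
    when observation ``i`` is absent; missing entries are dropped before any
    computation.
    """

    probe_id: str
    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.times.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.missing_mask)):
            raise ValueError(f"profile {self.probe_id!r}: times, values and missing_mask lengths differ")
        if not np.all(np.isfinite(self.times)):
            raise ValueError(f"profile {self.probe_id!r}: non-finite time coordinate")
        # values may be NaN only where masked missing
        self.missing_mask = self.missing_mask | ~np.isfinite(self.values)

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) with missing entries dropped."""
        keep = ~self.missing_mask
        return self.times[keep], self.values[keep]

    def centred(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Observed (times, values - mean, mean); GP fits are zero-mean."""
        t, y = self.observed()
        mu = float(y.mean()) if y.size else 0.0
        return t, y - mu, mu

    def ml_variance(self) -> float:
        """Maximum-likelihood (1/N) variance of the centred observations."""
        _, y, _ = self.centred()
        return float(np.mean(y * y)) if y.size else 0.0


@dataclass(frozen=True)
class GPFit:
    """Result of a hyperparameter optimisation run."""

    hyperparams: SEHyperparams
    lml: float
    converged: bool
    n_iterations: int
    init_label: str = ""


@dataclass(frozen=True)
class PredictiveDistribution:
    """Pointwise GP predictive mean and variance at query times."""

    query_times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    includes_observation_noise: bool


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


def _se_cross(times_a: np.ndarray, times_b: np.ndarray, hyp: SEHyperparams) -> np.ndarray:
    """Noise-free SE cross-covariance sigma_f^2 * exp(-d^2 / (2 l^2))."""
    a = np.asarray(times_a, dtype=float).reshape(-1, 1)
    b = np.asarray(times_b, dtype=float).reshape(1, -1)
    if math.isinf(hyp.lengthscale_sq):
        return np.full((a.shape[0], b.shape[1]), hyp.signal_variance)
    d2 = (a - b) ** 2
    return hyp.signal_variance * np.exp(-d2 / (2.0 * hyp.lengthscale_sq))


def se_kernel(times_a, times_b, hyp: SEHyperparams) -> np.ndarray:
    """Noisy univariate SE covariance matrix between two sets of times.

    The white-noise term ``sigma_n^2`` is added on the diagonal only when
    ``times_a`` and ``times_b`` are the same sequence (a self-covariance):
    noise is attached to observation indices, not to time coordinates, so two
    distinct observations at a repeated time coordinate share no noise.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("time coordinates must be finite")
    K = _se_cross(a, b, hyp)
    self_cov = times_a is times_b or (a.shape == b.shape and np.array_equal(a, b))
    if self_cov and hyp.noise_variance > 0:
        K = K + hyp.noise_variance * np.eye(len(a))
    return K


# ---------------------------------------------------------------------------
# Log-marginal likelihood
# ---------------------------------------------------------------------------


def _chol_with_jitter(K: np.ndarray, probe_id: str = "<profile>"):
    """Cholesky of K, escalating diagonal jitter on failure.

    Returns (cho_factor result, jitter actually used)."""
    n = K.shape[0]
    mean_diag = float(np.mean(np.diag(K)))
    if mean_diag <= 0:
        mean_diag = 1.0
    jitter = 0.0
    rel = _JITTER_START
    while True:
        try:
            return cho_factor(K + jitter * np.eye(n), lower=True), jitter
        except np.linalg.LinAlgError:
            if rel > _JITTER_MAX:
                raise ConditioningError(
                    f"covariance for profile {probe_id!r} is not positive definite "
                    f"after relative jitter {_JITTER_MAX:g}"
                ) from None
            jitter = rel * mean_diag
            rel *= 10.0


def _lml_terms(t: np.ndarray, y: np.ndarray, hyp: SEHyperparams, probe_id: str):
    """Shared plumbing: returns (K_y, cho, alpha, lml)."""
    K = _se_cross(t, t, hyp)
    K[np.diag_indices_from(K)] += hyp.noise_variance
    cho, _ = _chol_with_jitter(K, probe_id)
    alpha = cho_solve(cho, y)
    L = cho[0]
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    n = len(y)
    lml = -0.5 * float(y @ alpha) - 0.5 * logdet - n * _HALF_LOG_2PI
    return K, cho, alpha, lml


def log_marginal_likelihood(profile: TimeCourseProfile, hyp: SEHyperparams) -> float:
    """Log-marginal likelihood of the centred profile under the SE-GP.

    Computes ``-1/2 y^T K_y^{-1} y - 1/2 log|K_y| - (N/2) log 2pi`` through a
    Cholesky factorisation of ``K_y = K_f + sigma_n^2 I``; translation of all
    times by a constant leaves the value unchanged (stationary kernel).
    """
    t, y, _ = profile.centred()
    return _lml_terms(t, y, hyp, profile.probe_id)[3]


def lml_gradient(profile: TimeCourseProfile, hyp: SEHyperparams) -> np.ndarray:
    """Gradient of the LML over ``(log l^2, log sigma_f^2, log sigma_n^2)``.

    Uses the trace identity ``dL/dtheta = 1/2 tr((alpha alpha^T - K_y^{-1})
    dK/dtheta)`` with ``alpha = K_y^{-1} y``, chain-ruled to log-parameters
    for unconstrained optimisation.  A coordinate at its degenerate boundary
    (``sigma_f^2 = 0``, or the constant-kernel limit ``l^2 = inf``) gets a
    zero gradient component.
    """
    t, y, _ = profile.centred()
    K, cho, alpha, _ = _lml_terms(t, y, hyp, profile.probe_id)
    n = len(y)
    Kinv = cho_solve(cho, np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # dL/dtheta = 1/2 tr(A dK/dtheta)

    grad = np.zeros(3)
    l2, sf2, sn2 = hyp.lengthscale_sq, hyp.signal_variance, hyp.noise_variance
    if math.isfinite(l2) and sf2 > 0:
        d2 = (t.reshape(-1, 1) - t.reshape(1, -1)) ** 2
        E = np.exp(-d2 / (2.0 * l2))
        # d K / d log l^2 = sigma_f^2 * E * d^2 / (2 l^2)
        dK = sf2 * E * d2 / (2.0 * l2)
        grad[0] = 0.5 * float(np.sum(A * dK))
        # d K / d log sigma_f^2 = sigma_f^2 * E
        grad[1] = 0.5 * float(np.sum(A * (sf2 * E)))
    elif sf2 > 0:  # constant-kernel limit: exponent factor is 1 everywhere
        grad[1] = 0.5 * sf2 * float(np.sum(A))
    if sn2 > 0:
        grad[2] = 0.5 * sn2 * float(np.trace(A))
    return grad


# ---------------------------------------------------------------------------
# Hyperparameter optimisation
# ---------------------------------------------------------------------------

# Box constraints on the log-parameters keep the optimizer away from regions
# where K_y is numerically degenerate or the kernel is effectively flat.
_LOG_L2_BOUNDS = (math.log(1e-3), math.log(1e8))
_LOG_SNR_BOUNDS = (-23.0, 23.0)  # snr in ~[1e-10, 1e10]
_LOG_VAR_BOUNDS = (math.log(1e-12), math.log(1e8))


def optimize_hyperparams(
    profile: TimeCourseProfile,
    init: SNRParams,
    constrain_variance_sum: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    init_label: str = "",
) -> GPFit:
    """Maximise the LML from ``init`` with a gradient-based optimizer.

    When ``constrain_variance_sum`` is True the search runs over
    ``(log l^2, log snr)`` with ``sigma_f^2 + sigma_n^2`` pinned to
    ``init.total_variance``; otherwise over all three log-hyperparameters.
    The returned fit never attains less than the LML at ``init`` (minus
    ``tol``): if the optimizer fails to improve, the init point is returned.
    Non-convergence within ``max_iter`` yields ``converged=False`` rather
    than an exception.
    """
    t, y, _ = profile.centred()
    pid = profile.probe_id

    if constrain_variance_sum:
        v = init.total_variance

        def unpack(x: np.ndarray) -> SEHyperparams:
            return SNRParams(math.exp(x[0]), math.exp(x[1]), v).to_hyperparams()

        def negobj(x: np.ndarray):
            hyp = unpack(x)
            _, _, _, lml = _lml_terms(t, y, hyp, pid)
            g3 = lml_gradient(profile, hyp)
            s = math.exp(x[1])
            # chain rule: log sf2 and log sn2 as functions of u = log snr
            gu = g3[1] * (1.0 / (1.0 + s)) + g3[2] * (-s / (1.0 + s))
            return -lml, -np.array([g3[0], gu])

        x0 = np.array([math.log(init.lengthscale_sq), math.log(max(init.snr, 1e-12))])
        bounds = [_LOG_L2_BOUNDS, _LOG_SNR_BOUNDS]
    else:
        h0 = init.to_hyperparams()

        def unpack(x: np.ndarray) -> SEHyperparams:
            return SEHyperparams(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]))

        def negobj(x: np.ndarray):
            hyp = unpack(x)
            _, _, _, lml = _lml_terms(t, y, hyp, pid)
            return -lml, -lml_gradient(profile, hyp)

        x0 = np.array([
            math.log(h0.lengthscale_sq),
            math.log(max(h0.signal_variance, 1e-12)),
            math.log(max(h0.noise_variance, 1e-12)),
        ])
        bounds = [_LOG_L2_BOUNDS, _LOG_VAR_BOUNDS, _LOG_VAR_BOUNDS]

    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    f0, _ = negobj(x0)
    res = minimize(
        negobj,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tol},
    )
    if -res.fun >= -f0 - tol:
        best_x, best_lml = res.x, -float(res.fun)
    else:  # ascent guarantee: never return worse than the init point
        best_x, best_lml = x0, -float(f0)
    return GPFit(
        hyperparams=unpack(best_x),
        lml=best_lml,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        init_label=init_label,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(
    profile: TimeCourseProfile,
    hyp: SEHyperparams,
    query_times,
    include_noise: bool = False,
) -> PredictiveDistribution:
    """GP predictive mean and pointwise variance at new time points.

    mean = k_*^T (K_f + sigma_n^2 I)^{-1} y and
    variance = k(x_*, x_*) - k_*^T (K_f + sigma_n^2 I)^{-1} k_*,
    plus ``sigma_n^2`` when ``include_noise``.  The prediction is of the
    centred profile's latent function shifted back by the profile mean.
    """
    xq = np.asarray(query_times, dtype=float)
    if not np.all(np.isfinite(xq)):
        raise ValueError("query_times must be finite")
    t, y, mu = profile.centred()
    K = _se_cross(t, t, hyp)
    K[np.diag_indices_from(K)] += hyp.noise_variance
    cho, jitter = _chol_with_jitter(K, profile.probe_id)
    Ks = _se_cross(xq, t, hyp)  # (Q, N)
    mean = Ks @ cho_solve(cho, y) + mu
    L = cho[0]
    V = solve_triangular(L, Ks.T, lower=True)  # (N, Q)
    var = hyp.signal_variance - np.einsum("ij,ij->j", V, V)
    if include_noise:
        var = var + hyp.noise_variance
    var = np.maximum(var, 0.0)
    return PredictiveDistribution(
        query_times=xq, mean=mean, variance=var, includes_observation_noise=include_noise
    )
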