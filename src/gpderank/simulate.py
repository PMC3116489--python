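"""In-silico expression time-course benchmarks with ground-truth labels.

Two generators, both returning a :class:`SimulatedDataset` of
:class:`~gpderank.gp_core.TimeCourseProfile` objects plus binary labels
(1 = differentially expressed):

* **GP benchmark** — differentially expressed (DE) profiles are draws from a
  zero-mean GP with SE kernel whose hyperparameters (l^2, sigma_f^2,
  sigma_n^2) are sampled from Gamma distributions fitted to typical
  significant microarray profiles; the remaining profiles are zero functions
  plus white Gaussian noise whose variance is the sum of one signal-variance
  and one noise-variance draw, so quiet profiles have a comparable scale.
  Defaults: 8000 profiles, 600 DE, 11 time points x 4 replicates.

* **Legendre benchmark** — DE profiles are random polynomials in an
  orthonormal Legendre basis on the rescaled interval [-1, 1] (degree drawn
  uniformly up to 6) plus i.i.d. noise that is Gaussian or Student-t with 5
  or 3 degrees of freedom; quiet profiles are pure noise.  This emulates the
  generating model of hierarchical-Bayes time-course methods built on
  finite polynomial bases.

All randomness flows from the config seed; generation is a pure function of
the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numpy.polynomial import legendre as npleg

from .gp_core import SEHyperparams, TimeCourseProfile, _se_cross

__all__ = [
    "GammaPrior",
    "GPSimConfig",
    "LegendreSimConfig",
    "SimulatedDataset",
    "sample_de_profile",
    "sample_null_profile",
    "simulate_gp_dataset",
    "simulate_legendre_dataset",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(a, b) sampling prior with a = scale, b = shape; mean = a*b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Gamma parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a * self.b

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(shape=self.b, scale=self.a, size=size)


def _default_timepoints() -> tuple[float, ...]:
    return tuple(float(t) for t in range(11))


@dataclass(frozen=True)
class GPSimConfig:
    """GP-sampled benchmark configuration (defaults are the study protocol)."""

    n_profiles: int = 8000
    n_de: int = 600
    timepoints: tuple[float, ...] = field(default_factory=_default_timepoints)
    n_replicates: int = 4
    lengthscale_prior: GammaPrior = GammaPrior(1.4, 5.7)
    signal_prior: GammaPrior = GammaPrior(2.76, 0.2)
    noise_prior: GammaPrior = GammaPrior(23.0, 0.008)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_profiles <= 0:
            raise ValueError("n_profiles must be positive")
        if not (0 <= self.n_de <= self.n_profiles):
            raise ValueError("n_de must satisfy 0 <= n_de <= n_profiles")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")


@dataclass(frozen=True)
class LegendreSimConfig:
    """Legendre-basis benchmark configuration."""

    n_profiles: int = 8000
    n_de: int = 600
    timepoints: tuple[float, ...] = field(default_factory=_default_timepoints)
    n_replicates: int = 2
    max_degree: int = 6
    coefficient_sd: float = 1.0
    noise_family: Literal["gaussian", "t5", "t3"] = "gaussian"
    noise_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_profiles <= 0:
            raise ValueError("n_profiles must be positive")
        if not (0 <= self.n_de <= self.n_profiles):
            raise ValueError("n_de must satisfy 0 <= n_de <= n_profiles")
        if not (1 <= self.max_degree):
            raise ValueError("max_degree must be >= 1")
        if self.noise_family not in ("gaussian", "t5", "t3"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        if self.coefficient_sd <= 0:
            raise ValueError("coefficient_sd must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class SimulatedDataset:
    """Profiles, aligned binary labels and per-profile generating parameters."""

    profiles: list[TimeCourseProfile]
    labels: np.ndarray
    config: object
    generating_params: list[object]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.profiles):
            raise ValueError("labels and profiles must be aligned")


def _obs_times(timepoints, n_replicates: int) -> np.ndarray:
    """Observation time vector: each time point repeated per replicate."""
    t = np.asarray(timepoints, dtype=float)
    return np.repeat(t, n_replicates)


def sample_de_profile(
    config: GPSimConfig, rng: np.random.Generator, probe_id: str = "de"
) -> tuple[TimeCourseProfile, SEHyperparams]:
    """One differentially expressed profile: GP draw with Gamma-sampled kernel.

    The latent function is drawn once per unique time point and shared across
    replicates; white noise N(0, sigma_n^2) is added per observation.
    """
    l2 = float(config.lengthscale_prior.sample(rng))
    sf2 = float(config.signal_prior.sample(rng))
    sn2 = float(config.noise_prior.sample(rng))
    hyp = SEHyperparams(l2, sf2, sn2)
    t = np.asarray(config.timepoints, dtype=float)
    Kf = _se_cross(t, t, hyp)
    f = rng.multivariate_normal(np.zeros(len(t)), Kf, method="eigh")
    obs_t = _obs_times(config.timepoints, config.n_replicates)
    f_obs = np.repeat(f, config.n_replicates)
    y = f_obs + rng.normal(0.0, math.sqrt(sn2), size=len(obs_t))
    return TimeCourseProfile(probe_id, obs_t, y), hyp


def sample_null_profile(
    config: GPSimConfig, rng: np.random.Generator, probe_id: str = "null"
) -> TimeCourseProfile:
    """One quiet profile: i.i.d. N(0, v) white noise at every observation,
    with v = (one signal-variance draw) + (one noise-variance draw) so quiet
    profiles match the scale of expressed ones."""
    v = float(config.signal_prior.sample(rng)) + float(config.noise_prior.sample(rng))
    obs_t = _obs_times(config.timepoints, config.n_replicates)
    y = rng.normal(0.0, math.sqrt(v), size=len(obs_t))
    return TimeCourseProfile(probe_id, obs_t, y)


def _label_positions(n_profiles: int, n_de: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(n_profiles, dtype=int)
    labels[rng.choice(n_profiles, size=n_de, replace=False)] = 1
    return labels


def _probe_id(i: int, width: int) -> str:
    return f"probe_{i:0{width}d}"


def simulate_gp_dataset(config: GPSimConfig = GPSimConfig()) -> SimulatedDataset:
    """Full GP benchmark: n_de GP-sampled DE profiles at uniformly random
    label positions, the rest white noise."""
    rng = np.random.default_rng(config.seed)
    labels = _label_positions(config.n_profiles, config.n_de, rng)
    width = len(str(config.n_profiles - 1))
    profiles: list[TimeCourseProfile] = []
    params: list[object] = []
    for i in range(config.n_profiles):
        pid = _probe_id(i, width)
        if labels[i]:
            p, hyp = sample_de_profile(config, rng, pid)
            params.append(hyp)
        else:
            p = sample_null_profile(config, rng, pid)
            params.append(None)
        profiles.append(p)
    return SimulatedDataset(profiles, labels, config, params)


def _orthonormal_legendre_design(t01: np.ndarray, max_deg: int) -> np.ndarray:
    """Columns k = 0..max_deg of sqrt((2k+1)/2) * P_k on x in [-1, 1].

    The scaling makes the basis orthonormal in L2([-1, 1])."""
    tmin, tmax = float(t01.min()), float(t01.max())
    span = tmax - tmin if tmax > tmin else 1.0
    x = 2.0 * (t01 - tmin) / span - 1.0
    cols = []
    for k in range(max_deg + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(math.sqrt((2 * k + 1) / 2.0) * npleg.legval(x, coef))
    return np.column_stack(cols)


def _noise(family: str, scale: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if family == "gaussian":
        return rng.normal(0.0, scale, size=size)
    df = 5 if family == "t5" else 3
    # scale is the t-distribution's scale parameter, not its std deviation
    return scale * rng.standard_t(df, size=size)


def simulate_legendre_dataset(config: LegendreSimConfig = LegendreSimConfig()) -> SimulatedDataset:
    """Legendre-basis benchmark: DE profiles are random orthonormal-Legendre
    polynomials (uniform degree 1..max_degree, N(0, coefficient_sd^2)
    coefficients) plus i.i.d. noise; quiet profiles are pure noise."""
    rng = np.random.default_rng(config.seed)
    labels = _label_positions(config.n_profiles, config.n_de, rng)
    obs_t = _obs_times(config.timepoints, config.n_replicates)
    design = _orthonormal_legendre_design(obs_t, config.max_degree)
    width = len(str(config.n_profiles - 1))
    profiles: list[TimeCourseProfile] = []
    params: list[object] = []
    n_obs = len(obs_t)
    for i in range(config.n_profiles):
        pid = _probe_id(i, width)
        eps = _noise(config.noise_family, config.noise_scale, n_obs, rng)
        if labels[i]:
            deg = int(rng.integers(1, config.max_degree + 1))
            coeffs = rng.normal(0.0, config.coefficient_sd, size=deg + 1)
            y = design[:, : deg + 1] @ coeffs + eps
            params.append({"degree": deg, "coefficients": coeffs})
        else:
            y = eps
            params.append(None)
        profiles.append(TimeCourseProfile(pid, obs_t, y))
    return SimulatedDataset(profiles, labels, config, params)
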