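"""Likelihood-ratio ranking of profiles by evidence of differential expression.

Each centred profile is scored by the log-ratio of GP marginal likelihoods
of two hypotheses that differ only through the SE-kernel hyperparameters:

* H0 (quiet gene): theta_1 = (l^2 -> inf, sigma_f^2 = 0, sigma_n^2 = var(y)) —
  a constant function whose observed variance is pure noise.  Its LML has the
  closed form ``-(N/2) (log(2 pi var(y)) + 1)`` because var(y) is the
  maximum-likelihood noise variance of the centred profile.
* H1 (differentially expressed): theta_2 initialised at a typical significant
  profile (l^2 = 20, nearly all variance assigned to signal) and adapted by
  maximising the LML over (log l^2, log SNR) with
  sigma_f^2 + sigma_n^2 = var(y).

score = LML(theta_2*) - LML(theta_1), in nats; larger means stronger
evidence of differential expression.  A whole dataset is ranked by
descending score, ties broken by probe id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .gp_core import GPFit, SEHyperparams, SNRParams, TimeCourseProfile, optimize_hyperparams

__all__ = [
    "RankRecord",
    "RankingConfig",
    "null_lml",
    "alternative_fit",
    "rank_score",
    "rank_dataset",
]

logger = logging.getLogger(__name__)

# Floor on var(y): a numerically constant profile is maximally quiet and is
# forced to rank last via a -inf score instead of raising.
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class RankingConfig:
    """Settings for the likelihood-ratio ranking.

    ``h1_lengthscale_inits`` are the l^2 values from which the H1 fit is
    started (one optimisation per value, best LML wins).  ``h1_snr_init``
    encodes the "(almost) no noise" H1 starting point: sigma_n^2 =
    var(y) / (1 + snr).  ``include_h0_as_h1_init`` adds the H0 configuration
    to the H1 candidate set, which guarantees score >= 0.
    """

    h1_lengthscale_inits: tuple[float, ...] = (20.0,)
    h1_snr_init: float = 1e3
    include_h0_as_h1_init: bool = False
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.h1_lengthscale_inits) == 0:
            raise ValueError("h1_lengthscale_inits must be non-empty")
        if any(l2 <= 0 or not math.isfinite(l2) for l2 in self.h1_lengthscale_inits):
            raise ValueError("h1_lengthscale_inits must be positive finite")


@dataclass(frozen=True)
class RankRecord:
    """Per-gene ranking outcome: LMLs under both hypotheses and their gap."""

    probe_id: str
    lml_h0: float
    lml_h1: float
    score: float
    best_fit: GPFit
    rank: int = 0
    degenerate: bool = False


def _checked_variance(profile: TimeCourseProfile) -> tuple[float, bool]:
    v = profile.ml_variance()
    if v < _VAR_FLOOR:
        return _VAR_FLOOR, True
    return v, False


def null_lml(profile: TimeCourseProfile) -> float:
    """Closed-form LML of the quiet-gene configuration theta_1.

    theta_1 = (l^2 -> inf, sigma_f^2 = 0, sigma_n^2 = var(y)) makes the
    centred observations i.i.d. N(0, var(y)); at the ML variance the
    log-density collapses to ``-(N/2) (log(2 pi var(y)) + 1)``.
    """
    v, _ = _checked_variance(profile)
    n = profile.n_observed
    return -0.5 * n * (math.log(2.0 * math.pi * v) + 1.0)


def alternative_fit(profile: TimeCourseProfile, config: RankingConfig = RankingConfig()) -> GPFit:
    """Optimised H1 fit: best LML over the configured initialisations.

    Each lengthscale init starts at theta_2 with sigma_f^2 =
    var(y) * snr / (1 + snr) and is optimised over (log l^2, log SNR) with
    the variance sum pinned to var(y).  If every run fails to converge the
    best non-converged fit is returned, flagged ``converged=False``.
    """
    v, _ = _checked_variance(profile)
    candidates: list[GPFit] = []
    for l2 in config.h1_lengthscale_inits:
        init = SNRParams(lengthscale_sq=l2, snr=config.h1_snr_init, total_variance=v)
        fit = optimize_hyperparams(
            profile,
            init,
            constrain_variance_sum=True,
            max_iter=config.max_iter,
            tol=config.tol,
            init_label=f"l2={l2:g}",
        )
        candidates.append(fit)
    if config.include_h0_as_h1_init:
        h0 = SEHyperparams(math.inf, 0.0, v)
        candidates.append(
            GPFit(hyperparams=h0, lml=null_lml(profile), converged=True, n_iterations=0, init_label="h0")
        )
    converged = [c for c in candidates if c.converged]
    pool = converged if converged else candidates
    return max(pool, key=lambda c: c.lml)


def rank_score(profile: TimeCourseProfile, config: RankingConfig = RankingConfig()) -> RankRecord:
    """Likelihood-ratio score of one profile (rank left unset).

    score = LML(H1 optimum) - LML(theta_1).  Degenerate (constant) profiles
    get a ``-inf`` sentinel score so they rank last.
    """
    _, deg = _checked_variance(profile)
    if deg:
        logger.warning("profile %s is (numerically) constant; score forced to -inf", profile.probe_id)
        h0 = null_lml(profile)
        fit = GPFit(
            hyperparams=SEHyperparams(math.inf, 0.0, _VAR_FLOOR),
            lml=h0, converged=True, n_iterations=0, init_label="degenerate",
        )
        return RankRecord(profile.probe_id, h0, h0, -math.inf, fit, degenerate=True)
    h0 = null_lml(profile)
    fit = alternative_fit(profile, config)
    return RankRecord(profile.probe_id, h0, fit.lml, fit.lml - h0, fit)


def rank_dataset(
    profiles: Iterable[TimeCourseProfile],
    config: RankingConfig = RankingConfig(),
) -> list[RankRecord]:
    """Score every profile and return records in rank order.

    Ranks descend by score with ties broken by probe id; per-gene scores do
    not depend on the input row order.  Duplicate probe ids are rejected.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty dataset")
    ids = [p.probe_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate probe_ids: {dupes[:5]}")
    records = []
    for i, p in enumerate(profiles):
        if p.n_observed < 3:
            raise ValueError(f"profile {p.probe_id!r} has fewer than 3 non-missing observations")
        logger.debug("scoring profile %d/%d: %s", i + 1, len(profiles), p.probe_id)
        records.append(rank_score(p, config))
    # stable two-pass sort: probe_id ascending, then score descending, so a
    # -inf sentinel ranks last and ties break alphabetically
    records.sort(key=lambda r: r.probe_id)
    records.sort(key=lambda r: r.score, reverse=True)
    return [
        RankRecord(r.probe_id, r.lml_h0, r.lml_h1, r.score, r.best_fit, rank=i + 1, degenerate=r.degenerate)
        for i, r in enumerate(records)
    ]
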