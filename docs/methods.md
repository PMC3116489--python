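# Methods

## Model

Each gene's centred profile `y` (log2 ratios at times `t`, replicates as
repeated time coordinates) is modelled as a zero-mean Gaussian process with
the noisy univariate squared-exponential covariance

    k(t_i, t_j) = σf² exp(−(t_i − t_j)²/(2ℓ²)) + σn² δ_ij.

`ℓ²` is the squared characteristic lengthscale in (time units)²: the
distance beyond which two time points decorrelate. `σf²` (signal variance)
and `σn²` (noise variance) split the observed variance between a smooth
latent function and white observation noise. `ℓ² = +∞` is the exact
constant-function limit (the exponential factor becomes 1 everywhere) and
is represented literally as `math.inf`; it is never handed to the
optimizer. Profiles are mean-centred per gene before fitting, and the
subtracted mean is restored in predictions. The profile variance `var(y)`
is the maximum-likelihood (1/N) variance of the centred, non-missing
observations, so the quiet-gene configuration below sits exactly at the ML
point of the i.i.d.-noise model.

The log-marginal likelihood (LML)

    L(θ) = −½ yᵀK_y⁻¹y − ½ log|K_y| − (N/2) log 2π,   K_y = K_f + σn² I

is computed through a Cholesky factorisation. Its analytic gradient uses
the trace identity ½ tr((ααᵀ − K_y⁻¹) ∂K_y/∂θ) with α = K_y⁻¹y,
chain-ruled to log-parameters; a coordinate at a degenerate boundary
(σf² = 0, or ℓ² = ∞) contributes a zero component rather than a −∞
log-coordinate.

## Hypotheses and score

* H₀ (quiet): θ₁ = (∞, 0, var(y)), fixed. Closed form
  L(θ₁) = −(N/2)(log 2π var(y)) + 1).
* H₁ (expressed): θ₂ starts at ℓ² = 20 (time units)², SNR = σf²/σn² = 10³
  (so σn² = var(y)/1001 — "almost no noise", kept strictly positive for
  conditioning), and is optimised over (log ℓ², log SNR) with
  σf² + σn² = var(y). The variance-sum constraint reduces the search to
  two dimensions and removes a family of spurious optima, because signal
  and noise variance compete to explain the same observed variance.

The score is L(θ₂*) − L(θ₁) in nats. It is invariant under adding a
constant to the profile (centring) and under rescaling the values (both
LMLs shift by −N log c). Multiple H₁ lengthscale initialisations (e.g.
{5, 20, 80}) are available through `RankingConfig`; the best LML wins, and
`include_h0_as_h1_init=True` adds θ₁ itself to the candidate set, which
clamps scores at ≥ 0. The method only ranks; it sets no significance
threshold — threshold selection belongs to the ROC analysis.

## Numerical choices

* **Optimizer.** L-BFGS-B on log-parameters with analytic gradients
  (`max_iter` 100, `gtol` 1e−6), with box bounds
  log ℓ² ∈ [log 1e−3, log 1e8], log SNR ∈ [−23, 23]. Any ascent-satisfying
  gradient optimizer is acceptable here; if a run ends below the starting
  LML, the start point is returned (ascent guarantee). Non-convergence is
  reported as `converged=False`, never as an exception.
* **Jitter.** On Cholesky failure, 1e−8·mean(diag) is added to the
  diagonal, escalating ×10 up to 1e−2·mean(diag); beyond that a
  conditioning error names the profile. For valid SE covariances this path
  is effectively never taken; it guards degenerate inputs such as all-equal
  times with σn² = 0.
* **Degenerate profiles.** var(y) is floored at 1e−12; a (numerically)
  constant profile gets score −∞ and ranks last — a constant profile is
  maximally quiet. Ties in score break by probe id for reproducible output.
* **Kernel self-covariance.** The δ (noise) term attaches to observation
  indices: it is added only when computing a covariance of a sequence with
  itself, so replicates at the same time coordinate share signal but not
  noise.

## Simulated benchmarks

The GP benchmark draws, per differentially expressed profile, (ℓ², σf²,
σn²) from Gamma priors Γ(scale a, shape b) with (a, b) = (1.4, 5.7),
(2.76, 0.2), (23, 0.008) — means 7.98, 0.552, 0.184 — then samples the
latent function at 11 equispaced time points (0..10, a configurable
default), copies it across 4 replicates and adds N(0, σn²) per
observation. Quiet profiles are white noise with variance equal to the sum
of one signal-variance and one noise-variance draw, giving them a scale
comparable to expressed profiles. Defaults: 8000 profiles, 600 expressed.
The shape/scale reading keeps the documented means but makes the signal
and noise priors extremely right-skewed (shapes 0.2 and 0.008), so a small
fraction of simulated profiles have near-zero variance; the −∞ sentinel
handles them. Replicate counts (4 for the GP benchmark, 2 for the
Legendre benchmark) are defaults, both configurable.

The Legendre benchmark builds expressed profiles as random polynomials in
the basis orthonormal on the rescaled interval [−1, 1] — degree uniform in
1..6, coefficients N(0, 1) — plus i.i.d. noise that is Gaussian or
Student-t with 5 or 3 degrees of freedom (`noise_scale`, default 0.5, is
the t-distribution's scale parameter, not its standard deviation). This
emulates the generating model of hierarchical-Bayes time-course methods
built on finite polynomial bases, without reproducing their full
coefficient hierarchy; quiet profiles are pure noise. Because the basis
has bounded degree while the SE kernel models infinitely differentiable
functions, the GP ranking is expected to do somewhat worse here than on
GP-sampled data — the benchmarks bracket the model-match question.

What the simulators do *not* emulate: probe-level intensity effects,
normalisation artefacts, heteroscedastic or correlated noise across genes,
and realistic missingness patterns. Passing benchmarks therefore
demonstrates correctness of the method and its power under the stated
generative models, not performance on any particular microarray platform.

## Evaluation

ROC curves sweep descending score thresholds (tied scores grouped); the
reported AUC is the Mann-Whitney statistic — the probability a random
expressed gene outranks a random quiet one, tied pairs counting ½ — and
agrees with the trapezoidal area of the curve to machine precision. The
curve construction is delegated to scikit-learn; the rank-statistic AUC is
computed independently so the two routes cross-check each other.

## Problem sizes used in validation

The test suite and acceptance script run the ranking benchmark at 200
profiles with 20 expressed (11 time points × 4 replicates), where the
score achieves AUC ≈ 0.96–1.0 across seeds; the bookkeeping check runs the
full 8000-profile protocol (generation only, a few seconds).

Hyperparameter recovery uses a single 200-observation profile simulated at
the Gamma-prior means. A Fisher-information analysis of candidate
observation grids showed that uniform grids over short spans leave
sd(log ℓ²) and sd(log σf²) near 0.25–0.3; the adopted grid — 100 pairs of
points 0.75 apart spread over [0, 300] — is the best of the candidates
(CRLB ≈ 0.22/0.20/0.14 for log ℓ²/log σf²/log σn²). Even so, single-profile
recovery of variance hyperparameters to 25% is close to the information
limit, so the recovery check in the acceptance script reports the measured
relative error rather than asserting it.

## Limitations

* Gaussian observation noise only; heavy-tailed (Student-t) noise models
  and periodic kernels are out of scope.
* Hyperparameters are optimised, not integrated over: the score is a
  likelihood-ratio approximation to a Bayes factor and has no calibrated
  null distribution; use the ranking (or ROC against external truth), not
  the raw score, for inference.
* One-dimensional inputs (time) only; one-sample design (log-ratio
  profiles), not two-sample condition comparison.
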