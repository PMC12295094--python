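# Methods

## Model

Observations (xₙ, tₙ), n = 1…N, follow a linear basis-function model

    tₙ = ωᵀψ(xₙ) + εₙ,   εₙ ~ N(0, λ⁻¹) i.i.d.,

with ψ: ℝᵈ → ℝᴹ a fixed feature map and λ > 0 the noise precision. Each
weight has an independent Gaussian prior ωᵢ ~ N(μᵢ, ηᵢ⁻¹). Setting μ ≡ 0
recovers the ARD prior of the relevance vector machine; the free-μ form is
its natural conjugate generalization. Because prior and likelihood are
jointly Gaussian in ω, the posterior is N(m, C) with C⁻¹ = Λ + λΨᵀΨ and
m = C(Λμ + λΨᵀT), Λ = diag(η), and the evidence p(T | X, η, λ, μ) is
available in closed form. Hyperparameters are chosen by maximizing the log
evidence (type-II maximum likelihood / empirical Bayes); no hyperpriors
are placed on (η, λ, μ).

The predictive distribution at a new input, with hyperparameters plugged
in at their optimized values, is Gaussian with mean mᵀψ(x*) and variance
1/λ + ψ(x*)ᵀCψ(x*). The variance formula is the standard Gaussian
marginalization of likelihood over the weight posterior; it is stated here
explicitly because only the predictive *form* is usually written down.

## EM algorithm

Treating ω as latent, ln p(T|·) = F(v) + KL(v ‖ p(ω|T,·)) for any density
v(ω). The E step sets v to the exact posterior (KL = 0), i.e. computes
(m, C). Maximizing the bound over the hyperparameters gives the M-step
laws ηᵢ = 1/(mᵢ² + Cᵢᵢ), λ = N/(‖T − Ψm‖² + Tr(ΨᵀΨC)), μ = m.

Two update schedules are implemented:

* **`as_printed`** (default): all three updates applied simultaneously
  from one E step. Note that with μ free, the bound's η-derivative
  actually yields the *centered* second moment (mᵢ − μᵢ)² + Cᵢᵢ; the
  simultaneous update with mᵢ² is therefore not a coordinate ascent of
  the bound, and the evidence trace is **not guaranteed monotone**. In
  practice it increases over the first iterations, plateaus, and then
  drifts very slowly along weakly identified directions (weights with
  mᵢ² ≲ Cᵢᵢ); reaching |Δ ln L| < 1e-6 typically takes hundreds of
  iterations at M = 10 even though the trace is visually flat after about
  ten.
* **`centered_sequential`**: ηᵢ ← 1/((mᵢ − μᵢ)² + Cᵢᵢ) with μ at its old
  value, then μ ← m, then λ. Each block maximizes the bound given the
  others, so the trace is monotonically non-decreasing (asserted in the
  tests to 1e-8 slack). With μ free this variant exposes an
  identifiability issue of the objective itself: the evidence can be
  driven arbitrarily high by letting the prior collapse onto the
  posterior mean (η → ∞ with μ = m), so the monotone ascent climbs until
  the precision cap and the posterior covariance approaches singularity.

With `mu_mode="fixed_zero"` the prior means are pinned at zero and both
schedules coincide — the classic RVM EM update. This is the mode in which
hyperparameter *recovery* is well posed (the collapse direction is
removed); the noise precision λ is recovered to within a few percent at
N = 500, M = 5 in the tests.

### Convergence and degeneracy policy

Convergence is declared on the scalar objective: |Δ ln L| < `tol`
(default 1e-6, absolute) between successive EM cycles, with one evidence
evaluation per cycle, `max_iter` = 1000 by default. Monitoring the
objective is far simpler than monitoring every hyperparameter and agrees
with it at a fixed point.

The posterior precision is factorized by Cholesky; its reciprocal
condition number (by symmetric eigenvalues) below 1e-12 triggers a
symmetric pseudo-inverse and flags the posterior. The fitting loop treats
a flagged posterior as a failed start: it redraws initial hyperparameters
from a reproducible seed stream (up to `max_restarts` = 20) before pushing
through on the pseudo-inverse, whose evidence values are imprecise and may
break monotonicity — the result is then marked `degenerate`. Weight
precisions are clipped at `eta_cap` = 1e12 to keep the collapse direction
from overflowing; caps are logged.

Initialization draws ln ηᵢ uniform on [ln 1e-3, ln 1e3], ln λ uniform on
[ln 1e-2, ln 1e2], μᵢ standard normal — broad, scale-free ranges spanning
the regimes the generator produces.

## Basis functions

`identity`, `polynomial` (scalar inputs) and `gaussian_rbf` families, with
an optional bias column ψ₀ ≡ 1 (on by default). For the RBF family the
package, unless told otherwise, takes the first k data points as centers
and the median pairwise distance of the inputs as the shared width — a
deterministic, data-scaled convention in the RVM tradition. Inputs are
taken as numeric; categorical encoding is the caller's concern.

## Synthetic generator

`bayesem.synthetic.generate` draws X uniform on [−1, 1]ᵈ (d = 1 by
default, box configurable), builds Ψ, draws ω from the prior and ε from
the noise model, and emits T = Ψω + ε along with the exact ground truth
(weights, hyperparameters, noise vector). When no hyperparameters are
supplied they are drawn from the same broad ranges as the EM
initialization. The generator matches the fitted model *exactly*; passing
recovery tests therefore demonstrates correctness of the estimation
machinery, not robustness to model misspecification (heteroscedastic
noise, non-Gaussian weights and correlated inputs are all outside what it
emulates).

## PSO baseline

Global-best PSO with 30 particles, inertia 0.72, cognitive = social =
1.49, velocities clamped to 20% of the box width — canonical
constriction-like settings. Particles live in (ln η, ln λ, μ); precisions
are searched in log space to respect positivity, with box ln η ∈ [−7, ln
eta_cap], ln λ ∈ [−7, 7], μ ∈ [−10, 10]. The objective is the same log
evidence, evaluated through cached Gram matrices (one M×M Cholesky per
evaluation). A "first converged iteration" is recorded as the first index
at which the best objective has changed by less than the EM tolerance over
a 50-iteration patience window, so the EM-vs-PSO comparison uses one
criterion; since a global-best trace only moves on strict improvement,
stagnation stretches can fire this detector mid-search even when the
objective later resumes improving — the detector measures stalling, not
optimality.

## Numerical choices

* All evidence computation is in log space; ln|C| = −ln|Λ + λΨᵀΨ| via
  Cholesky, falling back to a symmetric-eigenvalue log-determinant with a
  1e-300 floor in the pseudo-inverse regime.
* C is materialized (the updates need Cᵢᵢ and Tr(ΨᵀΨC)) and explicitly
  symmetrized as (C + Cᵀ)/2; mean solves go through the Cholesky factor.
* ΨᵀΨ and ΨᵀT are cached per dataset.
* N < M is allowed (the precision is still positive-definite in exact
  arithmetic) but warned about.
* Fixed-point self-consistency checks in the tests run the loop at
  tol = 1e-9: the default 1e-6 stopping rule leaves a parameter residual
  of the same order, so the fixed point must be resolved tighter than the
  property being asserted.

## Problem sizes used in the measurement script

`scripts/acceptance.py` uses N = 100 observations with the default
RBF basis at M = 10 (bias + 9 centers), 20 EM runs capped at 3000
iterations for the convergence-speed census, and a single 10,000-iteration
PSO run — sizes chosen to match the synthetic study the method is
demonstrated on while keeping the whole script under a minute.

## Known limitations

* With μ free the evidence is unbounded along the prior-collapse ridge;
  the reported optimum is a fixed point of the update laws, not a global
  maximizer, and different starts reach different fixed points.
* The `as_printed` schedule has no ascent guarantee (see above); use
  `centered_sequential` when monotonicity matters.
* Single-output regression only; no basis pruning/sparsification; no
  hyperpriors or full Bayesian model comparison.
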