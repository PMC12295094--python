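"""Global-best particle swarm optimization of the same evidence objective.

A derivative-free baseline against which the EM algorithm is compared: a
swarm of particles moves through the hyperparameter space, each attracted
toward its own best position (cognitive term) and the swarm's best position
(social term), with inertia carrying momentum:

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),   x <- x + v

Positions encode ``(ln eta_1..M, ln lam, mu_1..M)`` — precisions are
searched in log space to respect positivity — and the objective is the log
marginal likelihood.  The global-best trace is non-decreasing by
construction; "convergence" is declared at the first iteration after which
the best objective has changed by less than a tolerance over a patience
window, mirroring the EM stopping rule so the two methods are compared
under one criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .basis import RegressionData
from .errors import ConfigError, NumericalError
from .evidence import EvidenceEvaluator
from .posterior import Hyperparameters

__all__ = ["PSOConfig", "PSOResult", "pso_fit", "maximize", "default_bounds"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings (canonical inertia-weight values by default).

    ``velocity_clamp`` is a fraction of each dimension's box width; the
    convergence detector uses ``tol`` over a ``patience``-iteration window.
    """

    n_particles: int = 30
    n_iterations: int = 1000
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    velocity_clamp: float = 0.2
    bounds: np.ndarray | None = None  # (dims, 2); None = default box for the data
    tol: float = 1e-6
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ConfigError("need at least 2 particles")
        if self.n_iterations < 1:
            raise ConfigError("need at least 1 iteration")
        if not 0 < self.inertia < 1:
            raise ConfigError(f"inertia must lie in (0, 1), got {self.inertia}")
        if self.cognitive <= 0 or self.social <= 0:
            raise ConfigError("cognitive and social weights must be positive")
        if not self.velocity_clamp > 0:
            raise ConfigError("velocity_clamp must be positive")
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or not np.all(np.isfinite(b)):
                raise ConfigError("bounds must be a finite (dims, 2) array")
            if np.any(b[:, 1] <= b[:, 0]):
                raise ConfigError("each bound must have lower < upper")
            object.__setattr__(self, "bounds", b)


@dataclass
class PSOResult:
    """Best point found, its objective, the per-iteration global-best trace
    and the first iteration at which the stopping criterion was met
    (``None`` when it never was)."""

    best_hp: Hyperparameters
    best_log_evidence: float
    trace: np.ndarray
    first_converged_iteration: int | None


def default_bounds(n_basis: int, eta_cap: float = 1e12) -> np.ndarray:
    """Search box in transformed space: ln eta in [-7, ln eta_cap],
    ln lam in [-7, 7], mu in [-10, 10]."""
    bounds = np.empty((2 * n_basis + 1, 2))
    bounds[:n_basis] = (-7.0, np.log(eta_cap))
    bounds[n_basis] = (-7.0, 7.0)
    bounds[n_basis + 1 :] = (-10.0, 10.0)
    return bounds


def _first_converged(trace: np.ndarray, tol: float, patience: int) -> int | None:
    """First 1-based iteration k such that every step change within the
    trailing ``patience`` iterations is below ``tol``."""
    if trace.size <= patience:
        return None
    deltas = np.abs(np.diff(trace))
    below = deltas < tol
    run = 0
    for i, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= patience:
            return i + 2  # diff index i spans iterations (i+1, i+2), 1-based
    return None


def maximize(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    config: PSOConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Generic global-best PSO maximization of ``objective`` over a box.

    Returns ``(best_position, best_value, per_iteration_best_trace)``.
    Exposed separately from :func:`pso_fit` so the optimizer can be
    exercised on analytic test objectives.
    """
    bounds = np.asarray(bounds, dtype=float)
    dims = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    vmax = config.velocity_clamp * width
    rng = np.random.default_rng(config.seed)

    def evaluate(positions: np.ndarray) -> np.ndarray:
        return np.array([objective(p) for p in positions])

    x = rng.uniform(lo, hi, size=(config.n_particles, dims))
    v = rng.uniform(-vmax, vmax, size=(config.n_particles, dims))
    fx = evaluate(x)
    if not np.any(np.isfinite(fx)):
        x = rng.uniform(lo, hi, size=(config.n_particles, dims))
        fx = evaluate(x)
        if not np.any(np.isfinite(fx)):
            raise NumericalError("all particles yield a non-finite objective at initialization")

    pbest_x = x.copy()
    pbest_f = fx.copy()
    g = int(np.argmax(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    trace = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        r1 = rng.random((config.n_particles, dims))
        r2 = rng.random((config.n_particles, dims))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        np.clip(v, -vmax, vmax, out=v)
        x = np.clip(x + v, lo, hi)
        fx = evaluate(x)
        improved = fx > pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fx[improved]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace[it] = gbest_f
    return gbest_x, gbest_f, trace


def pso_fit(data: RegressionData, config: PSOConfig | None = None) -> PSOResult:
    """Maximize the log evidence over (ln eta, ln lam, mu) with PSO."""
    config = config or PSOConfig()
    M = data.n_basis
    bounds = config.bounds if config.bounds is not None else default_bounds(M)
    if bounds.shape[0] != 2 * M + 1:
        raise ConfigError(
            f"bounds describe {bounds.shape[0]} dimensions; expected {2 * M + 1} for M={M}"
        )
    evaluator = EvidenceEvaluator(data)

    def objective(z: np.ndarray) -> float:
        return evaluator.log_marginal(np.exp(z[:M]), float(np.exp(z[M])), z[M + 1 :])

    z, f, trace = maximize(objective, bounds, config)
    hp = Hyperparameters(eta=np.exp(z[:M]), lam=float(np.exp(z[M])), mu=z[M + 1 :])
    return PSOResult(
        best_hp=hp,
        best_log_evidence=f,
        trace=trace,
        first_converged_iteration=_first_converged(trace, config.tol, config.patience),
    )
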