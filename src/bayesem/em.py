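"""EM algorithm for evidence maximization over (eta, lam, mu).

Treating the weights as latent variables, the log evidence L decomposes as
``L = F(v) + KL(v || posterior)`` for any distribution v over the weights.
The E step sets v to the exact Gaussian posterior (KL = 0), which reduces to
computing the posterior mean m and covariance C.  The M step maximizes the
bound over the hyperparameters, giving the closed-form updates

    eta_i <- 1 / (m_i^2 + C_ii)
    lam   <- N / (||T - Psi m||^2 + Tr(Psi^T Psi C))
    mu    <- m

The loop monitors the log evidence and declares convergence when its
absolute change drops below a tolerance; checking the scalar objective is
far easier than checking convergence of every hyperparameter, and the two
coincide at a fixed point.

Two M-step variants are provided.  ``as_printed`` (default) applies the
three updates above simultaneously from one E step.  Note the eta update
uses m_i^2 rather than the centered (m_i - mu_i)^2 that the bound's
eta-derivative yields when mu is free; the simultaneous update is therefore
not guaranteed to increase the evidence at every step.
``centered_sequential`` is a coordinate-ascent variant — eta from
(m_i - mu_old_i)^2 + C_ii with mu held fixed, then mu <- m, then lam — each
stage maximizing the bound in one block, so the evidence trace is
monotonically non-decreasing.  With ``mu_mode="fixed_zero"`` the prior means
are pinned at zero (the classic RVM / sparse-Bayesian prior) and both
variants coincide.

Ill-conditioned posterior precisions are handled the pragmatic way: by
default the run restarts from fresh random hyperparameters (up to
``max_restarts`` times), after which it proceeds on the pseudo-inverse
covariance, which is imprecise and can stall the likelihood increase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .basis import RegressionData
from .errors import DegenerateFitError, NumericalError
from .evidence import EvidenceValue, log_marginal_likelihood
from .posterior import (
    RCOND_THRESHOLD,
    Hyperparameters,
    Posterior,
    compute_posterior,
)

__all__ = [
    "EMConfig",
    "FitResult",
    "TraceRecord",
    "e_step",
    "m_step",
    "initialize_hyperparameters",
    "fit",
]

logger = logging.getLogger(__name__)

#: Sampling ranges for random initialization: log-uniform for the precisions
#: (scale parameters), standard normal for the prior means.
ETA_INIT_RANGE = (1e-3, 1e3)
LAM_INIT_RANGE = (1e-2, 1e2)


@dataclass(frozen=True)
class EMConfig:
    """Loop control for :func:`fit`.

    Parameters
    ----------
    tol:
        Absolute change in log evidence below which the run is converged.
    max_iter:
        Maximum number of EM cycles per start.
    update_variant:
        ``as_printed`` (simultaneous updates) or ``centered_sequential``
        (monotone coordinate ascent); see the module docstring.
    mu_mode:
        ``free`` re-estimates the prior means; ``fixed_zero`` pins them at 0
        (RVM prior).
    max_restarts:
        How many times to redraw the initial hyperparameters when the
        posterior precision is numerically singular.
    singular_action:
        ``restart`` (default) or ``pseudo_inverse`` (skip restarting and
        push through on the pseudo-inverse covariance).
    eta_cap:
        Upper clip for the weight precisions, preventing overflow-driven
        singularity when a prior collapses onto a weight.
    seed:
        Seeds initialization and the restart stream.
    """

    tol: float = 1e-6
    max_iter: int = 1000
    update_variant: str = "as_printed"
    mu_mode: str = "free"
    max_restarts: int = 20
    singular_action: str = "restart"
    eta_cap: float = 1e12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.update_variant not in ("as_printed", "centered_sequential"):
            raise ValueError(f"unknown update_variant {self.update_variant!r}")
        if self.mu_mode not in ("free", "fixed_zero"):
            raise ValueError(f"unknown mu_mode {self.mu_mode!r}")
        if self.singular_action not in ("restart", "pseudo_inverse"):
            raise ValueError(f"unknown singular_action {self.singular_action!r}")
        if not self.eta_cap > 1:
            raise ValueError("eta_cap must exceed 1")
        if self.max_restarts < 0:
            raise ValueError("max_restarts must be >= 0")


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    log_evidence: float
    used_pseudo_inverse: bool


@dataclass
class FitResult:
    """Outcome of an EM run: final hyperparameters, final posterior, the
    per-iteration log-evidence trace and convergence status."""

    hyperparameters: Hyperparameters
    posterior: Posterior
    trace: list[TraceRecord]
    status: str  # converged | max_iter_reached | degenerate
    n_restarts: int = 0

    @property
    def log_evidence(self) -> float:
        return self.trace[-1].log_evidence

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def initialize_hyperparameters(M: int, seed: int | np.random.Generator) -> Hyperparameters:
    """Draw random starting hyperparameters.

    eta_i log-uniform on [1e-3, 1e3], lam log-uniform on [1e-2, 1e2],
    mu_i standard normal; deterministic for a given seed.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    eta = np.exp(rng.uniform(np.log(ETA_INIT_RANGE[0]), np.log(ETA_INIT_RANGE[1]), size=M))
    lam = float(np.exp(rng.uniform(np.log(LAM_INIT_RANGE[0]), np.log(LAM_INIT_RANGE[1]))))
    mu = rng.standard_normal(M)
    return Hyperparameters(eta=eta, lam=lam, mu=mu)


def e_step(hp: Hyperparameters, data: RegressionData) -> Posterior:
    """E step: the exact weight posterior N(m, C) under the current
    hyperparameters (zeroing the KL term of the bound)."""
    return compute_posterior(hp, data)


def m_step(
    post: Posterior,
    hp_old: Hyperparameters,
    data: RegressionData,
    variant: str = "as_printed",
    mu_mode: str = "free",
    eta_cap: float = 1e12,
) -> Hyperparameters:
    """M step: re-estimate (eta, lam, mu) from the posterior moments.

    ``as_printed``: eta_i = 1/(m_i^2 + C_ii), lam = N/(rss + Tr(Psi^T Psi C)),
    mu = m, all from the same (m, C).  ``centered_sequential``: eta_i =
    1/((m_i - mu_old_i)^2 + C_ii) first, then mu = m, then lam.  With
    ``mu_mode="fixed_zero"`` mu stays 0 and the variants coincide.
    """
    m, C = post.m, post.C
    diag = np.diag(C)

    resid = data.T - data.Psi @ m
    lam_denom = float(resid @ resid + np.sum(data.gram * C))
    if lam_denom <= 0:
        raise DegenerateFitError(
            "residual power and posterior trace both vanished; lam update undefined"
        )

    if mu_mode == "fixed_zero":
        center = m
        mu_new = np.zeros_like(m)
    elif variant == "centered_sequential":
        center = m - hp_old.mu
        mu_new = m.copy()
    else:  # as_printed
        center = m
        mu_new = m.copy()

    eta_denom = center**2 + diag
    if np.any(eta_denom <= 0):
        raise DegenerateFitError("m_i^2 + C_ii vanished for some weight; eta update undefined")
    eta_new = np.minimum(1.0 / eta_denom, eta_cap)
    if np.any(1.0 / eta_denom > eta_cap):
        logger.warning("capped %d weight precision(s) at eta_cap=%g",
                       int(np.sum(1.0 / eta_denom > eta_cap)), eta_cap)

    lam_new = data.n_obs / lam_denom
    return Hyperparameters(eta=eta_new, lam=lam_new, mu=mu_new)


def _run_single(
    hp: Hyperparameters,
    data: RegressionData,
    config: EMConfig,
    allow_pinv: bool,
) -> tuple[FitResult | None, bool]:
    """One EM run from ``hp``.  Returns (result, singular_encountered); the
    result is None when a singularity occurred and pinv is not allowed."""
    trace: list[TraceRecord] = []
    prev: float | None = None
    post = e_step(hp, data)
    singular = post.used_pseudo_inverse
    if singular and not allow_pinv:
        return None, True
    status = "max_iter_reached"
    for it in range(1, config.max_iter + 1):
        hp = m_step(
            post,
            hp,
            data,
            variant=config.update_variant,
            mu_mode=config.mu_mode,
            eta_cap=config.eta_cap,
        )
        post = compute_posterior(hp, data)  # posterior under the new hp; reused as next E step
        if post.used_pseudo_inverse:
            singular = True
            if not allow_pinv:
                return None, True
        ev = log_marginal_likelihood(hp, data, posterior=post)
        trace.append(TraceRecord(it, ev.log_value, post.used_pseudo_inverse))
        logger.info("iter %d: log evidence %.8f%s", it, ev.log_value,
                    " [pinv]" if post.used_pseudo_inverse else "")
        if not np.isfinite(ev.log_value):
            if not allow_pinv:
                return None, True
            status = "degenerate"
            break
        if prev is not None and abs(ev.log_value - prev) < config.tol:
            status = "degenerate" if post.used_pseudo_inverse else "converged"
            break
        prev = ev.log_value
    return FitResult(hyperparameters=hp, posterior=post, trace=trace, status=status), singular


def fit(
    data: RegressionData,
    config: EMConfig | None = None,
    hp0: Hyperparameters | None = None,
) -> FitResult:
    """Run the EM loop to a fixed point of the evidence.

    Alternates E and M steps, evaluating the log evidence once per cycle,
    until its absolute change falls below ``config.tol`` or ``max_iter`` is
    reached.  On a numerically singular posterior precision the run restarts
    from fresh random hyperparameters (``singular_action="restart"``, up to
    ``max_restarts`` times, each start consuming a seed from a reproducible
    stream) before pushing through on the pseudo-inverse covariance.

    ``hp0`` fixes the first start (restarts are still random); otherwise the
    first start is drawn from ``config.seed``.
    """
    config = config or EMConfig()
    if data.n_obs < data.n_basis:
        warnings.warn(
            f"fewer observations (N={data.n_obs}) than basis functions (M={data.n_basis}); "
            "the fit is prior-dominated",
            stacklevel=2,
        )
    seed_seq = np.random.SeedSequence(config.seed)
    n_starts = 1 + config.max_restarts
    child_seeds = seed_seq.spawn(n_starts + 1)

    def start_hp(attempt: int) -> Hyperparameters:
        if attempt == 0 and hp0 is not None:
            return hp0
        return initialize_hyperparameters(
            data.n_basis, np.random.default_rng(child_seeds[attempt])
        )

    n_restarts = 0
    if config.singular_action == "restart":
        for attempt in range(n_starts):
            result, singular = _run_single(start_hp(attempt), data, config, allow_pinv=False)
            if result is not None:
                result.n_restarts = n_restarts
                return result
            n_restarts += 1
            logger.warning("singular posterior precision; restart %d", n_restarts)

    # Restarts exhausted (or disabled): push through with the pseudo-inverse.
    logger.warning("proceeding on the pseudo-inverse covariance path")
    hp = start_hp(0) if config.singular_action == "pseudo_inverse" else initialize_hyperparameters(
        data.n_basis, np.random.default_rng(child_seeds[n_starts])
    )
    result, _ = _run_single(hp, data, config, allow_pinv=True)
    if result is None or not np.isfinite(result.trace[-1].log_evidence):
        raise NumericalError(
            "pseudo-inverse path produced a non-finite evidence after exhausting restarts"
        )
    result.n_restarts = n_restarts
    return result
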