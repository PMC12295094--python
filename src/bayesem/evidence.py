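"""The evidence (marginal likelihood) of the targets given the hyperparameters.

Integrating the weights out of likelihood x prior gives the evidence

    p(T | X, eta, lam, mu) = (lam/2pi)^{N/2} |Lambda|^{1/2} |C|^{1/2} exp(-G(m))

with the energy

    G(m) = (lam/2) ||T - Psi m||^2 + (1/2) (m - mu)^T Lambda (m - mu)

where (m, C) are the posterior mean and covariance.  Its logarithm

    ln p = (N/2) ln lam - G(m) + (1/2) sum_i ln eta_i + (1/2) ln|C| - (N/2) ln 2pi

is the objective maximized over (eta, lam, mu); this is type-II maximum
likelihood (empirical Bayes).  All computation is in log space; ``ln|C|`` is
obtained as minus the log-determinant of the precision via Cholesky, with a
symmetric-eigenvalue fallback in the pseudo-inverse regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .basis import RegressionData
from .errors import DimensionError
from .posterior import Hyperparameters, Posterior, compute_posterior

__all__ = ["EvidenceValue", "energy_G", "log_marginal_likelihood", "EvidenceEvaluator"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EvidenceValue:
    """Log evidence together with its additive pieces.

    ``from_pseudo_inverse`` marks values computed from a degenerate
    (pseudo-inverse) posterior; these are imprecise and can break the
    monotone increase of an EM trace.
    """

    log_value: float
    g_of_m: float
    logdet_C: float
    logdet_Lambda: float
    from_pseudo_inverse: bool = False


def energy_G(m: np.ndarray, hp: Hyperparameters, data: RegressionData) -> float:
    """Quadratic energy: misfit plus deviation of the posterior mean from
    the prior mean, ``(lam/2)||T - Psi m||^2 + (1/2)(m-mu)^T Lambda (m-mu)``."""
    m = np.asarray(m, dtype=float).ravel()
    if m.size != data.n_basis or m.size != hp.n_basis:
        raise DimensionError(
            f"m has length {m.size}, Psi has {data.n_basis} columns, hp has {hp.n_basis}"
        )
    resid = data.T - data.Psi @ m
    dev = m - hp.mu
    return float(0.5 * hp.lam * resid @ resid + 0.5 * dev @ (hp.eta * dev))


def _logdet_cov(post: Posterior, P: np.ndarray) -> float:
    """ln|C| = -ln|P| via Cholesky of the precision; eigenvalue fallback with
    a floor when the precision is numerically singular."""
    if not post.used_pseudo_inverse:
        try:
            L = sla.cholesky(P, lower=True)
            return -2.0 * float(np.sum(np.log(np.diag(L))))
        except sla.LinAlgError:
            pass
    w = sla.eigvalsh(P)
    w = np.maximum(w, 1e-300)
    return -float(np.sum(np.log(w)))


def log_marginal_likelihood(
    hp: Hyperparameters,
    data: RegressionData,
    posterior: Posterior | None = None,
) -> EvidenceValue:
    """Evaluate the log evidence ``ln p(T | X, eta, lam, mu)``.

    ``posterior`` may be supplied to reuse an already-computed posterior for
    these exact hyperparameters (the EM loop does this); otherwise it is
    computed here.
    """
    if posterior is None:
        posterior = compute_posterior(hp, data)
    P = hp.lam * data.gram
    P = P + np.diag(hp.eta)
    g = energy_G(posterior.m, hp, data)
    logdet_C = _logdet_cov(posterior, P)
    logdet_Lambda = float(np.sum(np.log(hp.eta)))
    n = data.n_obs
    log_value = (
        0.5 * n * np.log(hp.lam)
        - g
        + 0.5 * logdet_Lambda
        + 0.5 * logdet_C
        - 0.5 * n * _LOG_2PI
    )
    return EvidenceValue(
        log_value=float(log_value),
        g_of_m=g,
        logdet_C=logdet_C,
        logdet_Lambda=logdet_Lambda,
        from_pseudo_inverse=posterior.used_pseudo_inverse,
    )


class EvidenceEvaluator:
    """Fast repeated evidence evaluation on a fixed dataset.

    Caches the Gram matrix ``Psi^T Psi``, the moment ``Psi^T T`` and
    ``T^T T`` so each call costs one M x M Cholesky instead of touching the
    N x M design matrix.  Returns ``-inf`` for hyperparameters whose
    precision is not numerically positive-definite (used as the objective of
    derivative-free optimizers, where a hard failure would abort the search).
    """

    def __init__(self, data: RegressionData) -> None:
        self._gram = data.gram
        self._moment = data.moment
        self._ttt = float(data.T @ data.T)
        self._n = data.n_obs
        self._m = data.n_basis

    def log_marginal(self, eta: np.ndarray, lam: float, mu: np.ndarray) -> float:
        P = lam * self._gram
        P[np.diag_indices_from(P)] += eta
        try:
            L = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            return -np.inf
        b = eta * mu + lam * self._moment
        m = sla.cho_solve((L, True), b)
        # ||T - Psi m||^2 through the cached Gram products
        rss = max(self._ttt - 2.0 * m @ self._moment + m @ (self._gram @ m), 0.0)
        dev = m - mu
        g = 0.5 * lam * rss + 0.5 * dev @ (eta * dev)
        logdet_C = -2.0 * float(np.sum(np.log(np.diag(L))))
        val = (
            0.5 * self._n * np.log(lam)
            - g
            + 0.5 * float(np.sum(np.log(eta)))
            + 0.5 * logdet_C
            - 0.5 * self._n * _LOG_2PI
        )
        return float(val) if np.isfinite(val) else -np.inf
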