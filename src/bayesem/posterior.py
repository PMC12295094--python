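"""Closed-form weight posteriors and the approximate predictive distribution.

The likelihood is Gaussian, ``t_n ~ N(w^T psi(x_n), 1/lam)`` with noise
precision ``lam``.  Two conjugate weight priors are supported:

* a per-weight Gaussian prior ``w_i ~ N(mu_i, 1/eta_i)`` with its own mean
  and precision for every weight — the automatic-relevance-determination
  (ARD) prior of the relevance vector machine generalized to nonzero means;
* an arbitrary Gaussian prior ``N(m0, C0)`` with full covariance.

Both yield a Gaussian posterior ``N(m, C)`` with

    C^{-1} = Lambda + lam * Psi^T Psi,        m = C (Lambda mu + lam Psi^T T)

(``Lambda = diag(eta)``), the full-covariance case replacing ``Lambda`` with
``C0^{-1}`` and ``Lambda mu`` with ``C0^{-1} m0``.  Solves go through a
Cholesky factorization of the precision matrix; when the precision is
numerically singular (reciprocal condition number below ``RCOND_THRESHOLD``)
the covariance falls back to a symmetric pseudo-inverse and the posterior is
flagged, so downstream code can restart or warn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .basis import BasisConfig, RegressionData, build_design_matrix
from .errors import (
    ConfigError,
    DegeneratePredictionError,
    DimensionError,
    NumericalError,
)

__all__ = [
    "Hyperparameters",
    "ConjugatePrior",
    "Posterior",
    "compute_posterior",
    "compute_posterior_conjugate",
    "predict",
    "RCOND_THRESHOLD",
]

#: Below this reciprocal condition number of the posterior precision the
#: covariance is computed with a pseudo-inverse and flagged.
RCOND_THRESHOLD = 1e-12


@dataclass
class Hyperparameters:
    """The objects being optimized: per-weight prior precisions and means,
    plus the noise precision.

    Attributes
    ----------
    eta : (M,) ndarray
        Prior precision of each weight (``> 0``).
    lam : float
        Noise precision (``> 0``); the noise variance is ``1/lam``.
    mu : (M,) ndarray
        Prior mean of each weight.
    """

    eta: np.ndarray
    lam: float
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float).ravel()
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.lam = float(self.lam)
        if self.eta.shape != self.mu.shape:
            raise DimensionError(
                f"eta has length {self.eta.size} but mu has length {self.mu.size}"
            )
        if self.eta.size < 1:
            raise DimensionError("need at least one weight")
        if not np.all(self.eta > 0) or not np.all(np.isfinite(self.eta)):
            raise ConfigError("all weight precisions eta_i must be positive and finite")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ConfigError(f"noise precision lam must be positive and finite, got {self.lam}")
        if not np.all(np.isfinite(self.mu)):
            raise ConfigError("prior means mu must be finite")

    @property
    def n_basis(self) -> int:
        return self.eta.size

    def to_dict(self) -> dict:
        return {
            "eta": self.eta.tolist(),
            "lambda": self.lam,
            "mu": self.mu.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(eta=np.asarray(d["eta"], dtype=float),
                   lam=float(d["lambda"]),
                   mu=np.asarray(d["mu"], dtype=float))


@dataclass
class ConjugatePrior:
    """Full-covariance Gaussian weight prior ``N(m0, C0)``."""

    m0: np.ndarray
    C0: np.ndarray

    def __post_init__(self) -> None:
        self.m0 = np.asarray(self.m0, dtype=float).ravel()
        self.C0 = np.asarray(self.C0, dtype=float)
        m = self.m0.size
        if self.C0.shape != (m, m):
            raise DimensionError(f"C0 must be {m} x {m}, got {self.C0.shape}")
        if not np.allclose(self.C0, self.C0.T, atol=1e-8):
            raise ConfigError("C0 must be symmetric")
        try:
            sla.cholesky(self.C0, lower=True)
        except sla.LinAlgError as exc:
            raise ConfigError("C0 must be positive-definite") from exc


@dataclass
class Posterior:
    """Gaussian posterior ``N(m, C)`` over the weights with conditioning
    diagnostics.

    ``rcond`` is the reciprocal condition number of the posterior precision;
    ``used_pseudo_inverse`` marks covariances obtained through the
    pseudo-inverse fallback (the posterior is then degenerate and downstream
    consumers should treat results as imprecise).
    """

    m: np.ndarray
    C: np.ndarray
    rcond: float
    used_pseudo_inverse: bool = False


def _posterior_from_precision(
    P: np.ndarray, b: np.ndarray, rcond_threshold: float
) -> Posterior:
    """Invert the precision ``P`` and solve ``P m = b``, with pinv fallback."""
    if not np.all(np.isfinite(P)) or not np.all(np.isfinite(b)):
        raise NumericalError("non-finite entries in the posterior precision system")
    M = P.shape[0]
    w = sla.eigvalsh(P)
    wmax = float(np.max(np.abs(w)))
    rcond = float(np.min(w) / wmax) if wmax > 0 else 0.0
    if rcond >= rcond_threshold:
        try:
            cf = sla.cho_factor(P, lower=True)
            C = sla.cho_solve(cf, np.eye(M))
            m = sla.cho_solve(cf, b)
            C = 0.5 * (C + C.T)
            return Posterior(m=m, C=C, rcond=rcond, used_pseudo_inverse=False)
        except sla.LinAlgError:
            pass  # fall through to the pseudo-inverse path
    C = sla.pinvh(P)
    C = 0.5 * (C + C.T)
    return Posterior(m=C @ b, C=C, rcond=rcond, used_pseudo_inverse=True)


def compute_posterior(
    hp: Hyperparameters,
    data: RegressionData,
    rcond_threshold: float = RCOND_THRESHOLD,
) -> Posterior:
    """Posterior over weights under the per-weight Gaussian prior.

    Precision ``P = diag(eta) + lam Psi^T Psi``; mean
    ``m = P^{-1} (eta * mu + lam Psi^T T)``.
    """
    if hp.n_basis != data.n_basis:
        raise DimensionError(
            f"hyperparameters describe {hp.n_basis} weights but Psi has {data.n_basis} columns"
        )
    P = hp.lam * data.gram
    P[np.diag_indices_from(P)] += hp.eta
    b = hp.eta * hp.mu + hp.lam * data.moment
    return _posterior_from_precision(P, b, rcond_threshold)


def compute_posterior_conjugate(
    prior: ConjugatePrior,
    lam: float,
    data: RegressionData,
    rcond_threshold: float = RCOND_THRESHOLD,
) -> Posterior:
    """Posterior over weights under an arbitrary Gaussian prior ``N(m0, C0)``.

    ``C_N^{-1} = C0^{-1} + lam Psi^T Psi`` and
    ``m_N = C_N (C0^{-1} m0 + lam Psi^T T)``.
    """
    if prior.m0.size != data.n_basis:
        raise DimensionError(
            f"prior describes {prior.m0.size} weights but Psi has {data.n_basis} columns"
        )
    lam = float(lam)
    if not lam > 0:
        raise ConfigError(f"noise precision must be positive, got {lam}")
    C0_inv = sla.inv(prior.C0)
    C0_inv = 0.5 * (C0_inv + C0_inv.T)
    P = C0_inv + lam * data.gram
    b = C0_inv @ prior.m0 + lam * data.moment
    return _posterior_from_precision(P, b, rcond_threshold)


def predict(
    x_star: np.ndarray,
    post: Posterior,
    lam: float,
    config: BasisConfig,
) -> tuple[float, float]:
    """Approximate predictive mean and variance at a new input.

    With the hyperparameters fixed at their optimized values, the predictive
    distribution is the Gaussian obtained by integrating the likelihood over
    the weight posterior:

        mean     = m^T psi(x*)
        variance = 1/lam + psi(x*)^T C psi(x*)

    i.e. irreducible noise plus weight uncertainty projected through the
    basis.
    """
    lam = float(lam)
    if not lam > 0:
        raise ConfigError(f"noise precision must be positive, got {lam}")
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    psi = build_design_matrix(x_star, config)[0]
    if psi.size != post.m.size:
        raise DimensionError(
            f"basis maps to {psi.size} features but posterior has {post.m.size} weights"
        )
    mean = float(post.m @ psi)
    var = 1.0 / lam + float(psi @ post.C @ psi)
    if var <= 0:
        raise DegeneratePredictionError(
            f"non-positive predictive variance {var:g} (pseudo-inverse covariance?)"
        )
    return mean, var
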