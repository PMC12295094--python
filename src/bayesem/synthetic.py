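"""Synthetic data drawn from the model's own generative process.

The generator follows the model exactly, so parameter-recovery tests have a
well-defined ground truth:

1. draw (or accept) hyperparameters eta, lam, mu;
2. draw inputs X uniformly on a box (default [-1, 1]^d) and build the
   design matrix Psi from a basis spec;
3. draw weights w_i ~ N(mu_i, 1/eta_i) independently;
4. draw noise eps_n ~ N(0, 1/lam) i.i.d. and set T = Psi w + eps.

Everything is reproducible from a single integer seed, and the ground truth
(weights, hyperparameters, noise vector) rides along with the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisConfig, RegressionData, build_design_matrix, resolve_basis
from .em import initialize_hyperparameters
from .errors import ConfigError
from .posterior import Hyperparameters

__all__ = ["SyntheticDataset", "generate"]


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it.

    ``data.T == data.Psi @ true_weights + noise`` holds exactly (to floating
    point) by construction.
    """

    data: RegressionData
    true_weights: np.ndarray
    true_hp: Hyperparameters
    noise: np.ndarray
    seed: int


def generate(
    n: int,
    basis: BasisConfig | None = None,
    hp: Hyperparameters | None = None,
    seed: int = 0,
    d: int = 1,
    x_bounds: tuple[float, float] = (-1.0, 1.0),
) -> SyntheticDataset:
    """Draw one synthetic dataset of ``n`` observations.

    Parameters
    ----------
    n:
        Number of observations (``>= 1``).
    basis:
        Basis spec; data-dependent RBF defaults are resolved against the
        drawn inputs.  Defaults to a Gaussian RBF basis with a bias column.
    hp:
        Ground-truth hyperparameters.  When ``None`` they are drawn
        randomly (log-uniform precisions, standard-normal means) from the
        same seed stream.
    seed:
        Seeds inputs, hyperparameters, weights and noise.
    d:
        Input dimension (scalar inputs by default).
    x_bounds:
        The uniform sampling box for the inputs, applied per coordinate.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if x_bounds[1] <= x_bounds[0]:
        raise ConfigError(f"empty input box {x_bounds}")
    basis = basis or BasisConfig()
    rng = np.random.default_rng(seed)

    X = rng.uniform(x_bounds[0], x_bounds[1], size=(n, d))
    basis = resolve_basis(basis, X)
    Psi = build_design_matrix(X, basis)
    M = Psi.shape[1]

    if hp is None:
        hp = initialize_hyperparameters(M, rng)
    elif hp.n_basis != M:
        raise ConfigError(
            f"hyperparameters describe {hp.n_basis} weights but the basis yields M={M}"
        )

    w = hp.mu + rng.standard_normal(M) / np.sqrt(hp.eta)
    eps = rng.standard_normal(n) / np.sqrt(hp.lam)
    T = Psi @ w + eps
    return SyntheticDataset(
        data=RegressionData(X, T, Psi, basis=basis),
        true_weights=w,
        true_hp=hp,
        noise=eps,
        seed=int(seed),
    )
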