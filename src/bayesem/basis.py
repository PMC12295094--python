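"""Basis-function design matrices for linear regression.

A linear basis-function model writes the regression function as
``y(x, w) = w^T psi(x)`` where ``psi`` maps a raw input ``x`` (a point in
R^d) to an M-vector of fixed nonlinear features.  The model stays linear in
the weights, so the Gaussian posterior over ``w`` remains closed form no
matter how nonlinear the basis is.  This module builds the N x M design
matrix ``Psi`` with ``Psi[n, j] = psi_j(x_n)`` for three families:

``identity``
    the raw coordinates themselves (ordinary linear regression),
``polynomial``
    powers ``x, x^2, ..., x^degree`` of a scalar input,
``gaussian_rbf``
    radial bumps ``exp(-||x - c||^2 / (2 width^2))`` around a set of centers.

An optional bias column ``psi_0 = 1`` is prepended (on by default, the
usual convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DimensionError, UnsupportedBasisError

__all__ = ["BasisConfig", "RegressionData", "build_design_matrix", "resolve_basis"]

_FAMILIES = ("identity", "polynomial", "gaussian_rbf")


@dataclass(frozen=True)
class BasisConfig:
    """Specification of a basis-function family.

    Parameters
    ----------
    family:
        One of ``identity``, ``polynomial``, ``gaussian_rbf``.
    include_bias:
        Prepend a constant column ``psi_0(x) = 1``.
    degree:
        Highest power for the polynomial family (``>= 1``).
    centers:
        RBF centers, one row per center, shape ``(k, d)``.  If omitted for
        the RBF family, :func:`resolve_basis` picks the first ``n_centers``
        data points.
    width:
        Shared RBF length-scale (``> 0``).  If omitted, :func:`resolve_basis`
        uses the median pairwise distance of the inputs.
    n_centers:
        How many centers :func:`resolve_basis` should take from the data
        when ``centers`` is not given explicitly.
    """

    family: str = "gaussian_rbf"
    include_bias: bool = True
    degree: int | None = None
    centers: np.ndarray | None = None
    width: float | None = None
    n_centers: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown basis family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "polynomial":
            if self.degree is None or int(self.degree) < 1:
                raise ConfigError("polynomial basis requires degree >= 1")
        if self.family == "gaussian_rbf":
            if self.width is not None and not self.width > 0:
                raise ConfigError(f"RBF width must be positive, got {self.width}")
            if self.centers is not None:
                centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
                if centers.shape[0] < 1:
                    raise ConfigError("RBF basis requires at least one center")
                object.__setattr__(self, "centers", centers)

    def n_columns(self, d: int) -> int:
        """Number of design-matrix columns M for inputs of dimension ``d``."""
        bias = 1 if self.include_bias else 0
        if self.family == "identity":
            return bias + d
        if self.family == "polynomial":
            return bias + int(self.degree)
        if self.centers is None:
            raise ConfigError("RBF centers not resolved; call resolve_basis first")
        return bias + self.centers.shape[0]

    def to_dict(self) -> dict:
        out: dict = {"family": self.family, "include_bias": self.include_bias}
        if self.degree is not None:
            out["degree"] = int(self.degree)
        if self.width is not None:
            out["width"] = float(self.width)
        if self.centers is not None:
            out["centers"] = np.asarray(self.centers).tolist()
        if self.n_centers is not None:
            out["n_centers"] = int(self.n_centers)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "BasisConfig":
        known = {"family", "include_bias", "degree", "width", "centers", "n_centers"}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown basis config keys: {sorted(extra)}")
        kw = dict(d)
        if kw.get("centers") is not None:
            kw["centers"] = np.atleast_2d(np.asarray(kw["centers"], dtype=float))
        return cls(**kw)


def resolve_basis(config: BasisConfig, X: np.ndarray) -> BasisConfig:
    """Fill data-dependent RBF defaults (centers, width) from the inputs.

    Centers default to the first ``n_centers`` rows of ``X`` (``n_centers``
    defaults to ``min(N, 10) - bias``); the width defaults to the median
    pairwise Euclidean distance between distinct input points (or 1.0 when
    all points coincide).  Identity and polynomial configs pass through
    unchanged.
    """
    if config.family != "gaussian_rbf":
        return config
    X = _as_matrix(X)
    centers = config.centers
    if centers is None:
        k = config.n_centers
        if k is None:
            k = max(1, min(X.shape[0], 10) - (1 if config.include_bias else 0))
        if k > X.shape[0]:
            raise ConfigError(f"n_centers={k} exceeds the number of data points N={X.shape[0]}")
        centers = X[:k].copy()
    width = config.width
    if width is None:
        width = _median_pairwise_distance(X)
    return replace(config, centers=centers, width=float(width), n_centers=None)


def _median_pairwise_distance(X: np.ndarray, max_points: int = 512) -> float:
    pts = X[:max_points]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(pts.shape[0], k=1)
    vals = dist[iu]
    vals = vals[vals > 0]
    return float(np.median(vals)) if vals.size else 1.0


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise DimensionError(f"X must be an N x d matrix, got ndim={X.ndim}")
    return X


def build_design_matrix(X: np.ndarray, config: BasisConfig) -> np.ndarray:
    """Evaluate the basis functions on every input row.

    Returns the N x M matrix with entry ``[n, j] = psi_j(x_n)``; the bias
    column, when requested, is column 0.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if n < 1:
        raise DimensionError("need at least one input row")

    if config.family == "identity":
        cols = [X]
    elif config.family == "polynomial":
        if X.shape[1] != 1:
            raise UnsupportedBasisError(
                f"polynomial basis is defined for scalar inputs, got d={X.shape[1]}"
            )
        x = X[:, 0]
        cols = [x[:, None] ** p for p in range(1, int(config.degree) + 1)]
    else:  # gaussian_rbf
        if config.centers is None or config.width is None:
            raise ConfigError("RBF basis needs centers and width; call resolve_basis first")
        if config.centers.shape[1] != X.shape[1]:
            raise DimensionError(
                f"center dimension {config.centers.shape[1]} != input dimension {X.shape[1]}"
            )
        sq = ((X[:, None, :] - config.centers[None, :, :]) ** 2).sum(axis=-1)
        cols = [np.exp(-sq / (2.0 * config.width**2))]

    Psi = np.hstack(cols)
    if config.include_bias:
        Psi = np.hstack([np.ones((n, 1)), Psi])
    if not np.all(np.isfinite(Psi)):
        raise ConfigError("design matrix contains non-finite entries")
    return Psi


class RegressionData:
    """Inputs, targets and the derived design matrix, bundled.

    Attributes
    ----------
    X : (N, d) ndarray
        Raw inputs, one row per observation.
    T : (N,) ndarray
        Targets.
    Psi : (N, M) ndarray
        Design matrix of basis-function evaluations.
    basis : BasisConfig or None
        The (resolved) basis that produced ``Psi``, kept for prediction.
    """

    def __init__(
        self,
        X: np.ndarray,
        T: np.ndarray,
        Psi: np.ndarray,
        basis: BasisConfig | None = None,
    ) -> None:
        X = _as_matrix(X)
        T = np.asarray(T, dtype=float).ravel()
        Psi = np.asarray(Psi, dtype=float)
        if Psi.ndim != 2:
            raise DimensionError("Psi must be an N x M matrix")
        if not (X.shape[0] == T.shape[0] == Psi.shape[0]):
            raise DimensionError(
                f"row counts disagree: X has {X.shape[0]}, T has {T.shape[0]}, Psi has {Psi.shape[0]}"
            )
        if not np.all(np.isfinite(Psi)):
            raise DimensionError("Psi contains non-finite entries")
        self.X = X
        self.T = T
        self.Psi = Psi
        self.basis = basis
        self._gram: np.ndarray | None = None
        self._moment: np.ndarray | None = None

    @classmethod
    def from_arrays(cls, X: np.ndarray, T: np.ndarray, basis: BasisConfig) -> "RegressionData":
        """Build the design matrix from raw inputs and a basis spec."""
        X = _as_matrix(X)
        basis = resolve_basis(basis, X)
        return cls(X, T, build_design_matrix(X, basis), basis=basis)

    @property
    def n_obs(self) -> int:
        return self.Psi.shape[0]

    @property
    def n_basis(self) -> int:
        return self.Psi.shape[1]

    # Gram matrix Psi^T Psi and moment Psi^T T recur in every posterior and
    # evidence evaluation; cache them per dataset.
    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.Psi.T @ self.Psi
        return self._gram

    @property
    def moment(self) -> np.ndarray:
        if self._moment is None:
            self._moment = self.Psi.T @ self.T
        return self._moment
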