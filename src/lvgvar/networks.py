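"""Gaussian graphical model (GGM) and graphical VAR (GVAR) matrix algebra.

A GGM parameterizes a covariance matrix through a partial-correlation
matrix ``Omega`` (symmetric, zero diagonal, entries in (-1, 1)) and a
diagonal scaling matrix ``Delta`` on the standard-deviation scale::

    Sigma = Delta (I - Omega)^{-1} Delta

The GVAR adds a lag-1 regression matrix ``B`` whose innovations are
GGM-structured, yielding a *temporal* network (B) and a *contemporaneous*
network (Omega of the innovations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GaussianNetwork",
    "TemporalStructure",
    "NetworkError",
    "NotPositiveDefiniteError",
    "StationarityError",
    "network_to_covariance",
    "covariance_to_network",
    "implied_marginal_correlations",
    "stationary_covariance",
    "lag_covariance",
    "standardize_temporal",
    "check_stability",
    "edge_list",
]

#: (1 - rho) margin below which a temporal matrix counts as non-stationary.
STABILITY_TOL = 1e-6

#: smallest admissible eigenvalue (relative) in positive-definiteness checks.
PD_TOL = 1e-10


class NetworkError(ValueError):
    """Structurally invalid network input."""


class NotPositiveDefiniteError(NetworkError):
    """A matrix required to be positive definite is not."""


class StationarityError(NetworkError):
    """Temporal coefficient matrix has spectral radius >= 1."""


def _as_square(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NetworkError(f"{name} must be a square matrix, got shape {a.shape}")
    return a


def _require_pd(a: np.ndarray, name: str) -> None:
    """Symmetric positive-definiteness check with tolerance ``PD_TOL``."""
    sym = (a + a.T) / 2.0
    try:
        np.linalg.cholesky(sym)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(f"{name} is not positive definite") from None
    if np.linalg.eigvalsh(sym)[0] <= PD_TOL * max(1.0, float(np.abs(a).max())):
        raise NotPositiveDefiniteError(f"{name} is not positive definite")


@dataclass
class GaussianNetwork:
    """Partial-correlation network with diagonal scaling.

    Parameters
    ----------
    omega : array
        Symmetric partial-correlation matrix, zero diagonal, |entries| < 1.
    delta : array
        Positive scaling entries (SD scale), either a vector or a diagonal
        matrix.  Defaults to unit scaling.
    mask : array of bool, optional
        Edge-inclusion matrix; ``mask[i, j] is False`` forces
        ``omega[i, j] == 0``.  Defaults to the support of ``omega``.
    """

    omega: np.ndarray
    delta: np.ndarray = None
    mask: np.ndarray = None
    labels: list = field(default=None)

    def __post_init__(self):
        self.omega = _as_square(self.omega, "omega")
        p = self.omega.shape[0]
        if not np.allclose(self.omega, self.omega.T, atol=1e-12):
            raise NetworkError("omega must be symmetric")
        if np.any(np.abs(np.diag(self.omega)) > 1e-12):
            raise NetworkError("omega must have a zero diagonal")
        if np.any(np.abs(self.omega) >= 1.0):
            raise NetworkError("partial correlations must lie in (-1, 1)")
        if self.delta is None:
            self.delta = np.ones(p)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim == 2:
            self.delta = np.diag(self.delta)
        if self.delta.shape != (p,):
            raise NetworkError("delta must have one entry per node")
        if np.any(self.delta <= 0):
            raise NetworkError("delta entries must be strictly positive")
        if self.mask is None:
            self.mask = self.omega != 0.0
            np.fill_diagonal(self.mask, False)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (p, p) or not (self.mask == self.mask.T).all():
            raise NetworkError("mask must be square symmetric")
        if np.any(np.diag(self.mask)):
            raise NetworkError("mask diagonal must be False")
        if np.any(self.omega[~self.mask] != 0.0):
            raise NetworkError("omega has nonzero entries outside the mask")
        if self.labels is None:
            self.labels = [f"V{i + 1}" for i in range(p)]

    @property
    def n_nodes(self) -> int:
        return self.omega.shape[0]

    def to_edge_frame(self) -> pd.DataFrame:
        """Weighted edge list over the upper triangle (node_i, node_j, weight, included)."""
        p = self.n_nodes
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "node_i": self.labels[i],
                        "node_j": self.labels[j],
                        "weight": self.omega[i, j],
                        "included": bool(self.mask[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.labels, columns=self.labels)


@dataclass
class TemporalStructure:
    """Lag-1 GVAR: temporal coefficients ``beta`` plus GGM innovations."""

    beta: np.ndarray
    innovation: GaussianNetwork

    def __post_init__(self):
        self.beta = _as_square(self.beta, "beta")
        if self.beta.shape[0] != self.innovation.n_nodes:
            raise NetworkError("beta and innovation network dimensions differ")
        radius, stable = check_stability(self.beta)
        if not stable:
            raise StationarityError(
                f"temporal matrix has spectral radius {radius:.6f} >= 1"
            )

    @property
    def n_nodes(self) -> int:
        return self.beta.shape[0]


def network_to_covariance(net: GaussianNetwork) -> np.ndarray:
    """Covariance implied by a GGM: ``Delta (I - Omega)^{-1} Delta``."""
    p = net.n_nodes
    i_minus_omega = np.eye(p) - net.omega
    _require_pd(i_minus_omega, "(I - Omega)")
    inv = np.linalg.inv(i_minus_omega)
    d = net.delta
    sigma = d[:, None] * inv * d[None, :]
    return (sigma + sigma.T) / 2.0


def covariance_to_network(sigma, labels=None) -> GaussianNetwork:
    """Invert, standardize, and negate off-diagonals of a covariance matrix.

    Returns the GGM whose ``network_to_covariance`` reproduces ``sigma``:
    with ``K = Sigma^{-1}``, ``omega_ij = -k_ij / sqrt(k_ii k_jj)`` and
    ``delta_i = k_ii^{-1/2}``.
    """
    sigma = _as_square(sigma, "sigma")
    if not np.allclose(sigma, sigma.T, atol=1e-8 * max(1.0, np.abs(sigma).max())):
        raise NetworkError("sigma must be symmetric")
    _require_pd(sigma, "sigma")
    kappa = np.linalg.inv(sigma)
    d = np.sqrt(np.diag(kappa))
    omega = -kappa / np.outer(d, d)
    np.fill_diagonal(omega, 0.0)
    omega = (omega + omega.T) / 2.0
    return GaussianNetwork(omega=omega, delta=1.0 / d, labels=labels)


def implied_marginal_correlations(net: GaussianNetwork) -> np.ndarray:
    """Marginal correlation matrix implied by the partial-correlation network.

    Independent of ``delta``: with ``K = (I - Omega)^{-1}`` the result is
    ``D^{-1/2} K D^{-1/2}``, ``D = diag(K)``.
    """
    p = net.n_nodes
    i_minus_omega = np.eye(p) - net.omega
    _require_pd(i_minus_omega, "(I - Omega)")
    k = np.linalg.inv(i_minus_omega)
    d = np.sqrt(np.diag(k))
    r = k / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def stationary_covariance(temporal: TemporalStructure) -> np.ndarray:
    """Stationary (lag-0) covariance of the latent GVAR process.

    Solves ``vec(Sigma0) = (I (x) I - B (x) B)^{-1} vec(Sigma_innov)``,
    i.e. the discrete Lyapunov equation ``Sigma0 = B Sigma0 B' + Sigma_innov``.
    """
    b = temporal.beta
    p = b.shape[0]
    sigma_innov = network_to_covariance(temporal.innovation)
    lhs = np.eye(p * p) - np.kron(b, b)
    vec = np.linalg.solve(lhs, sigma_innov.reshape(-1, order="F"))
    sigma0 = vec.reshape(p, p, order="F")
    return (sigma0 + sigma0.T) / 2.0


def lag_covariance(beta, sigma0, k: int) -> np.ndarray:
    """Lag-k covariance ``B^k Sigma0`` (rows index the later occasion)."""
    if int(k) != k or k < 0:
        raise ValueError(f"lag k must be a nonnegative integer, got {k}")
    beta = _as_square(beta, "beta")
    out = np.array(sigma0, dtype=float, copy=True)
    for _ in range(int(k)):
        out = beta @ out
    return out


def standardize_temporal(temporal: TemporalStructure) -> np.ndarray:
    """Standardize temporal coefficients to partial directed correlations.

    Uses ``PDC_ij = b_ij / sqrt(sigma_ii kappa_jj + b_ij^2)`` with ``sigma``
    the innovation covariance and ``kappa`` its inverse (Wild et al. 2010).
    Sign-preserving, bounded in (-1, 1), zero where B is zero.
    """
    b = temporal.beta
    sigma = network_to_covariance(temporal.innovation)
    kappa = np.linalg.inv(sigma)
    denom = np.sqrt(np.outer(np.diag(sigma), np.diag(kappa)) + b**2)
    return b / denom


def check_stability(beta) -> tuple[float, bool]:
    """Spectral radius of ``beta`` and whether it is inside the unit circle."""
    beta = _as_square(beta, "beta")
    radius = float(np.max(np.abs(np.linalg.eigvals(beta))))
    return radius, radius < 1.0 - STABILITY_TOL


def edge_list(weights, mask=None, labels=None, directed=False) -> pd.DataFrame:
    """Plain edge list for an arbitrary weights matrix (e.g. temporal B)."""
    w = _as_square(np.asarray(weights, dtype=float), "weights")
    p = w.shape[0]
    labels = labels or [f"V{i + 1}" for i in range(p)]
    if mask is None:
        mask = w != 0.0
    rows = []
    for i in range(p):
        for j in range(p):
            if not directed and j <= i:
                continue
            rows.append(
                {
                    "node_i": labels[i],
                    "node_j": labels[j],
                    "weight": w[i, j],
                    "included": bool(mask[i, j]),
                }
            )
    return pd.DataFrame(rows)
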