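"""Model specifications and implied moment structures.

A specification couples a linear factor measurement model (``y = tau +
Lambda eta + eps``) with latent network structures and compiles to a flat
parameter table plus a builder mapping parameter values to the implied
stacked mean vector and (block-)Toeplitz covariance matrix:

* :class:`TsModelSpec` — single-subject time series.  The stacked variable
  vector pairs consecutive occasions ``(y_t, y_{t+1})``; the leading block
  is kept *saturated* with its own unique parameters so that the data
  duplication inherent in the Toeplitz construction does not inflate the
  degrees of freedom.
* :class:`PanelModelSpec` — multi-wave panel data.  Wave blocks decompose
  into a stable between-subject part (GGM on latent means plus between
  residuals) and a stationary within-subject GVAR part; block ``(s, t)``
  depends only on ``|s - t|``.
* :class:`CrossSectionalSpec` — a plain observed-variable GGM with free
  means; the degenerate single-occasion member of the family, used mainly
  for calibration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .networks import StationarityError, check_stability

__all__ = [
    "MeasurementModel",
    "TsModelSpec",
    "PanelModelSpec",
    "CrossSectionalSpec",
    "Parameter",
    "CompiledModel",
    "compile_spec",
    "count_free_parameters",
    "degrees_of_freedom",
    "implied_observed_lagk",
    "ts_implied_moments",
    "ts_population_moments",
    "panel_implied_moments",
    "spec_to_config",
    "spec_from_config",
    "liss_measurement_model",
]

_TRANSFORMS = {
    "id": (lambda x: x, lambda t: t),
    "log": (np.log, np.exp),
    "atanh": (np.arctanh, np.tanh),
}


@dataclass
class Parameter:
    """One scalar model parameter and where it lives."""

    name: str
    family: str
    positions: list  # [(matrix_key, (i, j) or (i,))]
    free: bool
    value: float
    transform: str = "id"
    searchable: bool = False

    def to_unconstrained(self) -> float:
        return float(_TRANSFORMS[self.transform][0](self.value))

    @staticmethod
    def from_unconstrained(theta: float, transform: str) -> float:
        return float(_TRANSFORMS[transform][1](theta))


# ---------------------------------------------------------------------------
# measurement model
# ---------------------------------------------------------------------------


@dataclass
class MeasurementModel:
    """Factor measurement model with identification bookkeeping.

    Parameters
    ----------
    pattern : (n_y, n_eta) bool array
        Loading inclusion pattern; every factor needs at least one indicator.
    loadings : array, optional
        Start (or fixed) loading values on the pattern; default 1.
    loadings_free : bool array, optional
        Which loadings are estimated.  Default depends on ``identification``:
        ``"loadings"`` fixes the first included loading per factor,
        ``"scaling"`` frees all loadings and fixes the latent scalings to 1.
    tau / tau_free
        Intercepts (default start 0, free).
    residual_sd / residual_free
        Indicator residual standard deviations (default start 0.5, free).
        Stored on the SD scale so the implied variances are nonnegative by
        construction (the diagonal case of a triangular factorization).
    """

    pattern: np.ndarray
    loadings: np.ndarray = None
    loadings_free: np.ndarray = None
    tau: np.ndarray = None
    tau_free: np.ndarray = None
    residual_sd: np.ndarray = None
    residual_free: np.ndarray = None
    identification: str = "loadings"
    indicator_labels: list = None
    factor_labels: list = None

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=bool)
        n_y, n_eta = self.pattern.shape
        if not self.pattern.any(axis=0).all():
            raise ValueError("every factor needs at least one indicator")
        if self.identification not in ("loadings", "scaling"):
            raise ValueError("identification must be 'loadings' or 'scaling'")
        if self.loadings is None:
            self.loadings = self.pattern.astype(float)
        self.loadings = np.asarray(self.loadings, dtype=float) * self.pattern
        if self.loadings_free is None:
            free = self.pattern.copy()
            if self.identification == "loadings":
                for j in range(n_eta):
                    first = int(np.argmax(self.pattern[:, j]))
                    free[first, j] = False
            self.loadings_free = free
        self.loadings_free = np.asarray(self.loadings_free, dtype=bool) & self.pattern
        if self.tau is None:
            self.tau = np.zeros(n_y)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau_free is None:
            self.tau_free = np.ones(n_y, dtype=bool)
        self.tau_free = np.asarray(self.tau_free, dtype=bool)
        if self.residual_sd is None:
            self.residual_sd = np.full(n_y, 0.5)
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        if self.residual_free is None:
            self.residual_free = np.ones(n_y, dtype=bool)
        self.residual_free = np.asarray(self.residual_free, dtype=bool)
        if self.indicator_labels is None:
            self.indicator_labels = [f"y{i + 1}" for i in range(n_y)]
        if self.factor_labels is None:
            self.factor_labels = [f"eta{j + 1}" for j in range(n_eta)]

    @property
    def n_indicators(self) -> int:
        return self.pattern.shape[0]

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]

    @property
    def scalings_free(self) -> bool:
        return self.identification == "loadings"

    @classmethod
    def identity(cls, labels) -> "MeasurementModel":
        """Observed-variable reduction: Lambda = I fixed, residuals fixed 0."""
        p = len(labels)
        return cls(
            pattern=np.eye(p, dtype=bool),
            loadings=np.eye(p),
            loadings_free=np.zeros((p, p), dtype=bool),
            residual_sd=np.zeros(p),
            residual_free=np.zeros(p, dtype=bool),
            identification="loadings",
            indicator_labels=list(labels),
            factor_labels=list(labels),
        )


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------


def _full_offdiag(p: int) -> np.ndarray:
    m = np.ones((p, p), dtype=bool)
    np.fill_diagonal(m, False)
    return m


@dataclass
class TsModelSpec:
    """Single-subject latent GVAR on the paired-occasion Toeplitz layout."""

    measurement: MeasurementModel
    beta: np.ndarray = None
    beta_free: np.ndarray = None
    omega_zeta: np.ndarray = None
    omega_zeta_free: np.ndarray = None
    delta_zeta: np.ndarray = None

    kind: str = field(default="ts", init=False)

    def __post_init__(self):
        m = self.measurement.n_factors
        if self.beta is None:
            self.beta = 0.1 * np.eye(m)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta_free is None:
            self.beta_free = np.ones((m, m), dtype=bool)
        self.beta_free = np.asarray(self.beta_free, dtype=bool)
        if self.omega_zeta is None:
            self.omega_zeta = np.zeros((m, m))
        self.omega_zeta = np.asarray(self.omega_zeta, dtype=float)
        if self.omega_zeta_free is None:
            self.omega_zeta_free = _full_offdiag(m)
        self.omega_zeta_free = np.asarray(self.omega_zeta_free, dtype=bool)
        if self.delta_zeta is None:
            self.delta_zeta = np.ones(m)
        self.delta_zeta = np.asarray(self.delta_zeta, dtype=float)


@dataclass
class PanelModelSpec:
    """Multi-wave panel latent GVAR with a between-subject network."""

    measurement: MeasurementModel
    n_waves: int = 3
    beta: np.ndarray = None
    beta_free: np.ndarray = None
    omega_zeta: np.ndarray = None
    omega_zeta_free: np.ndarray = None
    delta_zeta: np.ndarray = None
    omega_between: np.ndarray = None
    omega_between_free: np.ndarray = None
    delta_between: np.ndarray = None
    delta_between_free: bool = True
    between_residual_sd: np.ndarray = None
    between_residual_free: np.ndarray = None
    wave_presence: np.ndarray = None  # (n_y, n_waves) bool

    kind: str = field(default="panel", init=False)

    def __post_init__(self):
        if self.n_waves < 3:
            raise ValueError("panel estimation requires at least three waves")
        m = self.measurement.n_factors
        n_y = self.measurement.n_indicators
        if self.beta is None:
            self.beta = 0.1 * np.eye(m)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta_free is None:
            self.beta_free = np.ones((m, m), dtype=bool)
        self.beta_free = np.asarray(self.beta_free, dtype=bool)
        if self.omega_zeta is None:
            self.omega_zeta = np.zeros((m, m))
        self.omega_zeta = np.asarray(self.omega_zeta, dtype=float)
        if self.omega_zeta_free is None:
            self.omega_zeta_free = _full_offdiag(m)
        self.omega_zeta_free = np.asarray(self.omega_zeta_free, dtype=bool)
        if self.delta_zeta is None:
            self.delta_zeta = np.ones(m)
        self.delta_zeta = np.asarray(self.delta_zeta, dtype=float)
        if self.omega_between is None:
            self.omega_between = np.zeros((m, m))
        self.omega_between = np.asarray(self.omega_between, dtype=float)
        if self.omega_between_free is None:
            self.omega_between_free = _full_offdiag(m)
        self.omega_between_free = np.asarray(self.omega_between_free, dtype=bool)
        if self.delta_between is None:
            self.delta_between = 0.5 * np.ones(m)
        self.delta_between = np.asarray(self.delta_between, dtype=float)
        if self.between_residual_sd is None:
            self.between_residual_sd = np.full(n_y, 0.3)
        self.between_residual_sd = np.asarray(self.between_residual_sd, dtype=float)
        if self.between_residual_free is None:
            self.between_residual_free = np.ones(n_y, dtype=bool)
        self.between_residual_free = np.asarray(self.between_residual_free, dtype=bool)
        if self.wave_presence is None:
            self.wave_presence = np.ones((n_y, self.n_waves), dtype=bool)
        self.wave_presence = np.asarray(self.wave_presence, dtype=bool)


@dataclass
class CrossSectionalSpec:
    """Observed-variable GGM with free means (calibration workhorse)."""

    labels: list
    omega: np.ndarray = None
    omega_free: np.ndarray = None
    delta: np.ndarray = None
    mu: np.ndarray = None

    kind: str = field(default="cross", init=False)

    def __post_init__(self):
        p = len(self.labels)
        if self.omega is None:
            self.omega = np.zeros((p, p))
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega_free is None:
            self.omega_free = _full_offdiag(p)
        self.omega_free = np.asarray(self.omega_free, dtype=bool)
        if self.delta is None:
            self.delta = np.ones(p)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.mu is None:
            self.mu = np.zeros(p)
        self.mu = np.asarray(self.mu, dtype=float)


# ---------------------------------------------------------------------------
# implied moment helpers (public, network-level)
# ---------------------------------------------------------------------------


def implied_observed_lagk(lam, latent_lagk, residual_cov, k: int) -> np.ndarray:
    """Observed lag-k (co)variances: ``Lambda S_k Lambda' (+ residuals iff k=0)``."""
    lam = np.asarray(lam, dtype=float)
    latent_lagk = np.asarray(latent_lagk, dtype=float)
    out = lam @ latent_lagk @ lam.T
    if k == 0:
        residual_cov = np.asarray(residual_cov, dtype=float)
        if residual_cov.shape != out.shape:
            raise ValueError("residual covariance has wrong shape")
        out = out + residual_cov
    return out


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


class CompiledModel:
    """Flat parameter table plus the matrices -> (mu, Sigma) builder."""

    def __init__(self, spec, params, template, var_labels):
        self.spec = spec
        self.params = params
        self._template = template  # dict matrix_key -> array with fixed values
        self.var_labels = var_labels
        self._index = {p.name: i for i, p in enumerate(params)}

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def n_stacked(self) -> int:
        return len(self.var_labels)

    @property
    def free_params(self):
        return [p for p in self.params if p.free]

    @property
    def free_names(self):
        return [p.name for p in self.params if p.free]

    def get(self, name: str) -> Parameter:
        return self.params[self._index[name]]

    def free_vector(self) -> np.ndarray:
        return np.array([p.value for p in self.params if p.free])

    def theta(self) -> np.ndarray:
        return np.array([p.to_unconstrained() for p in self.params if p.free])

    def set_free_vector(self, values) -> None:
        it = iter(np.asarray(values, dtype=float))
        for p in self.params:
            if p.free:
                p.value = float(next(it))

    def natural_from_theta(self, theta) -> np.ndarray:
        return np.array(
            [
                Parameter.from_unconstrained(t, p.transform)
                for t, p in zip(theta, (q for q in self.params if q.free))
            ]
        )

    def matrices(self, free_values=None) -> dict:
        mats = {k: v.copy() for k, v in self._template.items()}
        if free_values is None:
            free_values = self.free_vector()
        it = iter(np.asarray(free_values, dtype=float))
        for p in self.params:
            if not p.free:
                continue
            v = float(next(it))
            for key, idx in p.positions:
                mats[key][idx] = v
        return mats

    def moments(self, free_values=None):
        """Implied (mu, Sigma) for the stacked variable vector."""
        return _BUILDERS[self.spec.kind](self.matrices(free_values))

    # -- structure edits (search) --------------------------------------------

    def copy(self) -> "CompiledModel":
        new = CompiledModel(
            self.spec,
            copy.deepcopy(self.params),
            {k: v.copy() for k, v in self._template.items()},
            list(self.var_labels),
        )
        return new

    def with_fixed(self, name: str, value: float = 0.0) -> "CompiledModel":
        new = self.copy()
        p = new.get(name)
        p.free = False
        p.value = value
        for key, idx in p.positions:
            new._template[key][idx] = value
        return new

    def with_freed(self, name: str, start: float = 0.0) -> "CompiledModel":
        new = self.copy()
        p = new.get(name)
        p.free = True
        p.value = start
        return new

    def searchable(self, family=None):
        out = [p for p in self.params if p.searchable]
        if family is not None:
            out = [p for p in out if p.family == family]
        return out

    @property
    def search_families(self):
        return sorted({p.family for p in self.params if p.searchable})


def _measurement_params(mm: MeasurementModel, params, template):
    n_y, n_eta = mm.pattern.shape
    template["lambda"] = mm.loadings.copy()
    template["tau"] = mm.tau.copy()
    template["resid_sd"] = mm.residual_sd.copy()
    for i in range(n_y):
        for j in range(n_eta):
            if mm.pattern[i, j]:
                params.append(
                    Parameter(
                        name=f"lambda[{mm.indicator_labels[i]},{mm.factor_labels[j]}]",
                        family="loading",
                        positions=[("lambda", (i, j))],
                        free=bool(mm.loadings_free[i, j]),
                        value=float(mm.loadings[i, j]),
                    )
                )
    for i in range(n_y):
        params.append(
            Parameter(
                name=f"tau[{mm.indicator_labels[i]}]",
                family="intercept",
                positions=[("tau", (i,))],
                free=bool(mm.tau_free[i]),
                value=float(mm.tau[i]),
            )
        )
    for i in range(n_y):
        free = bool(mm.residual_free[i])
        params.append(
            Parameter(
                name=f"resid_sd[{mm.indicator_labels[i]}]",
                family="residual",
                positions=[("resid_sd", (i,))],
                free=free,
                value=float(mm.residual_sd[i]),
                transform="log" if free else "id",
            )
        )


def _network_params(params, template, key, family, values, free_mask, labels):
    """Symmetric partial-correlation entries (lower triangle, searchable)."""
    m = values.shape[0]
    template[key] = values.copy()
    for i in range(m):
        for j in range(i):
            params.append(
                Parameter(
                    name=f"{key}[{labels[i]},{labels[j]}]",
                    family=family,
                    positions=[(key, (i, j)), (key, (j, i))],
                    free=bool(free_mask[i, j]),
                    value=float(values[i, j]),
                    transform="atanh" if free_mask[i, j] else "id",
                    searchable=True,
                )
            )


def _temporal_params(params, template, beta, beta_free, labels):
    m = beta.shape[0]
    template["beta"] = beta.copy()
    for i in range(m):
        for j in range(m):
            params.append(
                Parameter(
                    name=f"beta[{labels[i]},{labels[j]}]",
                    family="temporal",
                    positions=[("beta", (i, j))],
                    free=bool(beta_free[i, j]),
                    value=float(beta[i, j]),
                    searchable=True,
                )
            )


def _scaling_params(params, template, key, family, values, free, labels):
    template[key] = values.copy()
    for i, lab in enumerate(labels):
        params.append(
            Parameter(
                name=f"{key}[{lab}]",
                family=family,
                positions=[(key, (i,))],
                free=bool(free),
                value=float(values[i]),
                transform="log" if free else "id",
            )
        )


def compile_spec(spec) -> CompiledModel:
    """Flatten a spec into a :class:`CompiledModel` parameter table."""
    params, template = [], {}
    if spec.kind == "ts":
        mm = spec.measurement
        _measurement_params(mm, params, template)
        _temporal_params(params, template, spec.beta, spec.beta_free, mm.factor_labels)
        _network_params(
            params, template, "omega_zeta", "contemporaneous",
            spec.omega_zeta, spec.omega_zeta_free, mm.factor_labels,
        )
        _scaling_params(
            params, template, "delta_zeta", "scaling",
            spec.delta_zeta, mm.scalings_free, mm.factor_labels,
        )
        # saturated lead block: unique mean and Cholesky-parameterized covariance
        n_y = mm.n_indicators
        template["mu_star"] = np.zeros(n_y)
        template["star_chol"] = np.eye(n_y)
        for i in range(n_y):
            params.append(
                Parameter(
                    name=f"mu_star[{mm.indicator_labels[i]}]",
                    family="star_mean",
                    positions=[("mu_star", (i,))],
                    free=True,
                    value=0.0,
                )
            )
        for i in range(n_y):
            for j in range(i + 1):
                params.append(
                    Parameter(
                        name=f"star_chol[{i + 1},{j + 1}]",
                        family="star_cov",
                        positions=[("star_chol", (i, j))],
                        free=True,
                        value=1.0 if i == j else 0.0,
                        transform="log" if i == j else "id",
                    )
                )
        labels = [f"{v}@prev" for v in mm.indicator_labels] + list(mm.indicator_labels)
        return CompiledModel(spec, params, template, labels)

    if spec.kind == "panel":
        mm = spec.measurement
        _measurement_params(mm, params, template)
        _temporal_params(params, template, spec.beta, spec.beta_free, mm.factor_labels)
        _network_params(
            params, template, "omega_zeta", "contemporaneous",
            spec.omega_zeta, spec.omega_zeta_free, mm.factor_labels,
        )
        _scaling_params(
            params, template, "delta_zeta", "scaling",
            spec.delta_zeta, mm.scalings_free, mm.factor_labels,
        )
        _network_params(
            params, template, "omega_between", "between",
            spec.omega_between, spec.omega_between_free, mm.factor_labels,
        )
        _scaling_params(
            params, template, "delta_between", "scaling_between",
            spec.delta_between, spec.delta_between_free, mm.factor_labels,
        )
        template["resid_between_sd"] = spec.between_residual_sd.copy()
        for i in range(mm.n_indicators):
            free = bool(spec.between_residual_free[i])
            params.append(
                Parameter(
                    name=f"resid_between_sd[{mm.indicator_labels[i]}]",
                    family="residual_between",
                    positions=[("resid_between_sd", (i,))],
                    free=free,
                    value=float(spec.between_residual_sd[i]),
                    transform="log" if free else "id",
                )
            )
        template["_n_waves"] = np.array([spec.n_waves])
        template["_presence"] = spec.wave_presence.astype(float)
        labels = [
            f"{v}@{w + 1}"
            for w in range(spec.n_waves)
            for vi, v in enumerate(mm.indicator_labels)
            if spec.wave_presence[vi, w]
        ]
        return CompiledModel(spec, params, template, labels)

    if spec.kind == "cross":
        p = len(spec.labels)
        template["mu"] = spec.mu.copy()
        for i in range(p):
            params.append(
                Parameter(
                    name=f"mu[{spec.labels[i]}]",
                    family="mean",
                    positions=[("mu", (i,))],
                    free=True,
                    value=float(spec.mu[i]),
                )
            )
        _network_params(
            params, template, "omega", "contemporaneous",
            spec.omega, spec.omega_free, spec.labels,
        )
        _scaling_params(
            params, template, "delta", "scaling", spec.delta, True, spec.labels
        )
        return CompiledModel(spec, params, template, list(spec.labels))

    raise ValueError(f"unknown spec kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# builders: matrices -> (mu, Sigma)
# ---------------------------------------------------------------------------


def _ggm_cov(omega, delta):
    """Fast-path GGM covariance for the optimizer's inner loop.

    Positive definiteness of (I - Omega) is enforced by the Cholesky
    factorization; full structural validation lives in GaussianNetwork.
    """
    from .networks import NotPositiveDefiniteError

    p = omega.shape[0]
    a = np.eye(p) - omega
    try:
        np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError("(I - Omega) is not positive definite") from None
    inv = np.linalg.inv(a)
    delta = np.asarray(delta, dtype=float)
    sigma = delta[:, None] * inv * delta[None, :]
    return (sigma + sigma.T) / 2.0


def _latent_stationary(beta, omega, delta):
    radius, stable = check_stability(beta)
    if not stable:
        raise StationarityError(f"temporal matrix spectral radius {radius:.4f} >= 1")
    sigma_innov = _ggm_cov(omega, delta)
    p = beta.shape[0]
    lhs = np.eye(p * p) - np.kron(beta, beta)
    sigma0 = np.linalg.solve(lhs, sigma_innov.reshape(-1, order="F")).reshape(
        p, p, order="F"
    )
    return (sigma0 + sigma0.T) / 2.0


def _build_ts(mats):
    lam, tau = mats["lambda"], mats["tau"]
    theta = np.diag(mats["resid_sd"] ** 2)
    sigma0_eta = _latent_stationary(mats["beta"], mats["omega_zeta"], mats["delta_zeta"])
    sigma1_eta = mats["beta"] @ sigma0_eta
    sigma0_y = lam @ sigma0_eta @ lam.T + theta
    sigma1_y = lam @ sigma1_eta @ lam.T
    l_star = np.tril(mats["star_chol"])
    sigma_star = l_star @ l_star.T
    n_y = lam.shape[0]
    sigma = np.empty((2 * n_y, 2 * n_y))
    sigma[:n_y, :n_y] = sigma_star
    sigma[:n_y, n_y:] = sigma1_y.T
    sigma[n_y:, :n_y] = sigma1_y
    sigma[n_y:, n_y:] = sigma0_y
    mu = np.concatenate([mats["mu_star"], tau])
    return mu, (sigma + sigma.T) / 2.0


def _build_panel(mats):
    lam, tau = mats["lambda"], mats["tau"]
    n_y = lam.shape[0]
    n_t = int(mats["_n_waves"][0])
    theta_w = np.diag(mats["resid_sd"] ** 2)
    theta_b = np.diag(mats["resid_between_sd"] ** 2)
    sigma0_eta = _latent_stationary(mats["beta"], mats["omega_zeta"], mats["delta_zeta"])
    sigma_b_y = lam @ _ggm_cov(mats["omega_between"], mats["delta_between"]) @ lam.T + theta_b
    # within lag-k observed blocks (rows index the later wave)
    lagk = [sigma0_eta]
    for _ in range(1, n_t):
        lagk.append(mats["beta"] @ lagk[-1])
    within = [lam @ s @ lam.T for s in lagk]
    within[0] = within[0] + theta_w
    sigma = np.empty((n_t * n_y, n_t * n_y))
    for s in range(n_t):
        for t in range(n_t):
            k = abs(s - t)
            block = within[k] if s >= t else within[k].T
            sigma[s * n_y:(s + 1) * n_y, t * n_y:(t + 1) * n_y] = sigma_b_y + block
    mu = np.tile(tau, n_t)
    presence = mats["_presence"].astype(bool)
    keep = np.concatenate([presence[:, w] for w in range(n_t)])
    if not keep.all():
        sigma = sigma[np.ix_(keep, keep)]
        mu = mu[keep]
    return mu, (sigma + sigma.T) / 2.0


def _build_cross(mats):
    return mats["mu"].copy(), _ggm_cov(mats["omega"], mats["delta"])


_BUILDERS = {"ts": _build_ts, "panel": _build_panel, "cross": _build_cross}


def ts_implied_moments(spec: TsModelSpec):
    """Stacked mean (length 2 n_y) and Toeplitz covariance of a ts spec.

    The lead block carries the saturated star parameters exactly as they
    are estimated; for the population moments of a generating model use
    :func:`ts_population_moments`.
    """
    return compile_spec(spec).moments()


def ts_population_moments(spec: TsModelSpec):
    """Population stacked moments of a generating ts spec.

    Identical to :func:`ts_implied_moments` except that the lead block and
    mean equal their stationary population values (lag-0 covariance and
    intercepts) instead of the saturated star parameters.
    """
    mats = compile_spec(spec).matrices()
    lam, tau = mats["lambda"], mats["tau"]
    theta = np.diag(mats["resid_sd"] ** 2)
    sigma0_eta = _latent_stationary(
        mats["beta"], mats["omega_zeta"], mats["delta_zeta"]
    )
    sigma0_y = lam @ sigma0_eta @ lam.T + theta
    sigma1_y = lam @ (mats["beta"] @ sigma0_eta) @ lam.T
    n_y = lam.shape[0]
    sigma = np.empty((2 * n_y, 2 * n_y))
    sigma[:n_y, :n_y] = sigma0_y
    sigma[:n_y, n_y:] = sigma1_y.T
    sigma[n_y:, :n_y] = sigma1_y
    sigma[n_y:, n_y:] = sigma0_y
    return np.concatenate([tau, tau]), (sigma + sigma.T) / 2.0


def panel_implied_moments(spec: PanelModelSpec):
    """Stacked mean (length n_t n_y) and block-Toeplitz covariance of a panel spec."""
    return compile_spec(spec).moments()


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def count_free_parameters(spec_or_model) -> int:
    model = _as_compiled(spec_or_model)
    return sum(1 for p in model.params if p.free)


def degrees_of_freedom(spec_or_model) -> int:
    """Observed first- and second-order moments minus free parameters.

    The saturated lead-block parameters of the ts layout count as free, so
    the data duplication of the Toeplitz construction never inflates df.
    """
    model = _as_compiled(spec_or_model)
    p = model.n_stacked
    n_moments = p + p * (p + 1) // 2
    return n_moments - count_free_parameters(model)


def _as_compiled(spec_or_model) -> CompiledModel:
    if isinstance(spec_or_model, CompiledModel):
        return spec_or_model
    return compile_spec(spec_or_model)


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------


def spec_to_config(spec) -> str:
    """Serialize a spec to a human-editable YAML document."""
    mm = spec.measurement
    factors = {}
    for j, f in enumerate(mm.factor_labels):
        factors[f] = [
            mm.indicator_labels[i] for i in range(mm.n_indicators) if mm.pattern[i, j]
        ]
    observed = (
        not mm.loadings_free.any()
        and not mm.residual_free.any()
        and np.array_equal(mm.loadings, np.eye(mm.n_indicators))
        and np.all(mm.residual_sd == 0.0)
    )
    doc = {
        "kind": spec.kind,
        "indicators": list(mm.indicator_labels),
        "factors": factors,
        "identification": mm.identification,
        "observed": bool(observed),
    }
    if spec.kind == "panel":
        doc["n_waves"] = int(spec.n_waves)
        doc["between_residual_fixed_zero"] = [
            mm.indicator_labels[i]
            for i in range(mm.n_indicators)
            if not spec.between_residual_free[i] and spec.between_residual_sd[i] == 0.0
        ]
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_config(text: str):
    """Build a fully connected spec from a YAML config (see spec_to_config)."""
    doc = yaml.safe_load(text)
    indicators = list(doc["indicators"])
    factor_labels = list(doc["factors"].keys())
    pattern = np.zeros((len(indicators), len(factor_labels)), dtype=bool)
    for j, f in enumerate(factor_labels):
        for item in doc["factors"][f]:
            pattern[indicators.index(item), j] = True
    if doc.get("observed"):
        mm = MeasurementModel.identity(indicators)
    else:
        mm = MeasurementModel(
            pattern=pattern,
            identification=doc.get("identification", "loadings"),
            indicator_labels=indicators,
            factor_labels=factor_labels,
        )
    if doc["kind"] == "ts":
        return TsModelSpec(measurement=mm)
    if doc["kind"] == "panel":
        fixed = doc.get("between_residual_fixed_zero", []) or []
        resid_free = np.array([lab not in fixed for lab in indicators])
        resid_sd = np.where(resid_free, 0.3, 0.0)
        return PanelModelSpec(
            measurement=mm,
            n_waves=int(doc.get("n_waves", 3)),
            between_residual_sd=resid_sd,
            between_residual_free=resid_free,
        )
    raise ValueError(f"unknown config kind {doc['kind']!r}")


def liss_measurement_model() -> MeasurementModel:
    """The 22-indicator / 6-factor personality measurement structure.

    Three-item self-esteem and pessimism/optimism (LOT-R) scales, the
    five-item Satisfaction With Life scale, and four-indicator short forms
    of PANAS positive and negative affect.
    """
    factors = {
        "SE": ["SE1", "SE2", "SE3"],
        "Pes": ["Pes1", "Pes2", "Pes3"],
        "Opt": ["Opt1", "Opt2", "Opt3"],
        "LS": ["LS1", "LS2", "LS3", "LS4", "LS5"],
        "PA": ["PA1", "PA2", "PA3", "PA4"],
        "NA": ["NA1", "NA2", "NA3", "NA4"],
    }
    indicators = [i for items in factors.values() for i in items]
    pattern = np.zeros((len(indicators), len(factors)), dtype=bool)
    for j, items in enumerate(factors.values()):
        for item in items:
            pattern[indicators.index(item), j] = True
    return MeasurementModel(
        pattern=pattern,
        indicator_labels=indicators,
        factor_labels=list(factors.keys()),
    )
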