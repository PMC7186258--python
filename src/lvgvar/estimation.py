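"""Maximum-likelihood estimation of lvgvar model specifications.

Models are fit by minimizing the multivariate-normal discrepancy

    F_ML = trace(S Sigma^{-1}) + (zbar - mu)' Sigma^{-1} (zbar - mu) + ln|Sigma|,

which is -2/n times the log-likelihood up to an additive constant, or its
full-information (FIML) generalization: a weighted sum of the same
expression over missingness-pattern groups, each restricted to the
observed variables of the group.  Optimization is quasi-Newton on an
unconstrained reparameterization (log scalings and residual SDs, atanh
partial correlations, raw temporal coefficients with a stationarity
penalty).  Gradients are exact in the moment structure — the derivative of
F with respect to (mu, Sigma) is analytic — and the Jacobian of the
parameter -> (mu, Sigma) map is obtained by central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .networks import NetworkError, NotPositiveDefiniteError
from .specs import CompiledModel, compile_spec, degrees_of_freedom

__all__ = [
    "MomentData",
    "FitResult",
    "DataError",
    "ml_fit_value",
    "fiml_fit_value",
    "fit",
    "saturated_fit_value",
    "standard_errors",
    "chi_square_and_indices",
    "compare",
    "score_information",
]

_PENALTY = 1e10
_FD_STEP = 1e-6


class DataError(ValueError):
    """Invalid or inconsistent data input."""


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class PatternGroup:
    indices: np.ndarray  # observed-variable indices, ascending
    n: int
    means: np.ndarray
    cov: np.ndarray  # divisor n_i; zero matrix when n_i == 1


@dataclass
class MomentData:
    """Sample moments plus missingness-pattern groups for FIML.

    ``cov`` uses divisor ``n`` (the ML-consistent estimator).  For
    incomplete data the top-level ``means``/``cov`` are available-case
    summaries used only for starting values; fitting uses the groups.
    """

    means: np.ndarray
    cov: np.ndarray
    n: int
    labels: list
    pattern_groups: list = field(default_factory=list)
    _saturated: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.labels)
        if self.cov.shape != (p, p) or self.means.shape != (p,):
            raise DataError("moment dimensions do not match labels")
        if not np.allclose(
            self.cov, self.cov.T, atol=1e-8 * max(1.0, np.nanmax(np.abs(self.cov)))
        ):
            raise DataError("covariance matrix must be symmetric")
        if not self.pattern_groups:
            self.pattern_groups = [
                PatternGroup(np.arange(p), int(self.n), self.means, self.cov)
            ]
        if sum(g.n for g in self.pattern_groups) != self.n:
            raise DataError("pattern group sizes must sum to n")

    @property
    def n_vars(self) -> int:
        return len(self.labels)

    @property
    def complete(self) -> bool:
        return (
            len(self.pattern_groups) == 1
            and len(self.pattern_groups[0].indices) == self.n_vars
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MomentData":
        """Build moments from a wide table; rows grouped by missingness pattern."""
        values = df.to_numpy(dtype=float)
        labels = list(df.columns)
        observed = ~np.isnan(values)
        if (~observed).all(axis=1).any():
            raise DataError("data contain rows with all values missing")
        n = values.shape[0]
        groups = []
        keys = [tuple(row) for row in observed]
        for key in sorted(set(keys), reverse=True):
            rows = values[[k == key for k in keys]]
            idx = np.flatnonzero(np.array(key))
            sub = rows[:, idx]
            m = sub.mean(axis=0)
            if len(sub) == 1:
                c = np.zeros((len(idx), len(idx)))
            else:
                d = sub - m
                c = d.T @ d / len(sub)
            groups.append(PatternGroup(idx, len(sub), m, c))
        # available-case summaries for starting values
        with np.errstate(invalid="ignore"):
            means = np.nanmean(values, axis=0)
            var = np.nanvar(values, axis=0)
        cov = np.diag(var)
        if len(groups) == 1 and len(groups[0].indices) == len(labels):
            means, cov = groups[0].means, groups[0].cov
        return cls(means=means, cov=cov, n=n, labels=labels, pattern_groups=groups)

    @classmethod
    def from_moments(cls, means, cov, n, labels) -> "MomentData":
        return cls(means=means, cov=cov, n=int(n), labels=list(labels))


# ---------------------------------------------------------------------------
# fit functions
# ---------------------------------------------------------------------------


def _chol_pieces(sigma):
    """Cholesky factor, log-determinant and inverse; raises if not PD."""
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError("implied covariance is not positive definite")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv = np.linalg.inv(sigma)
    return c, logdet, inv


def ml_fit_value(data: MomentData, mu, sigma) -> float:
    """Complete-data normal-theory discrepancy at (mu, sigma)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    _, logdet, inv = _chol_pieces(sigma)
    d = data.means - mu
    return float(np.sum(data.cov * inv) + d @ inv @ d + logdet)


def fiml_fit_value(data: MomentData, mu, sigma) -> float:
    """Missingness-pattern-weighted discrepancy; equals ML on complete data."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not data.pattern_groups:
        raise DataError("no missingness-pattern groups present")
    total = 0.0
    for g in data.pattern_groups:
        sub = sigma[np.ix_(g.indices, g.indices)]
        _, logdet, inv = _chol_pieces(sub)
        d = g.means - mu[g.indices]
        total += g.n * (float(np.sum(g.cov * inv) + d @ inv @ d + logdet))
    return total / data.n


def _fit_value(data, mu, sigma, method):
    return ml_fit_value(data, mu, sigma) if method == "ml" else fiml_fit_value(
        data, mu, sigma
    )


def _loglik_constant(data: MomentData, method: str) -> float:
    """Per-case average of p_i ln(2 pi), so -2 lnL = n (F + constant)."""
    if method == "ml":
        return data.n_vars * np.log(2 * np.pi)
    return sum(g.n * len(g.indices) for g in data.pattern_groups) / data.n * np.log(
        2 * np.pi
    )


# ---------------------------------------------------------------------------
# saturated and baseline fits
# ---------------------------------------------------------------------------


def saturated_fit_value(data: MomentData, method: str = "ml") -> float:
    """Minimum of the fit function over an unstructured (mu, Sigma).

    Complete data: the closed form ``p + ln|S|``.  Incomplete data: the
    saturated FIML solution is found by EM and the fit value evaluated there.
    """
    key = method
    if key in data._saturated:
        return data._saturated[key]
    if method == "ml" or data.complete:
        g = data.pattern_groups[0]
        if method == "ml" and not data.complete:
            raise DataError("ML estimation requires complete data")
        _, logdet, _ = _chol_pieces(g.cov)
        value = data.n_vars + logdet
    else:
        mu, sigma = _em_saturated(data)
        value = fiml_fit_value(data, mu, sigma)
    data._saturated[key] = value
    return value


def _em_saturated(data: MomentData, max_iter: int = 500, tol: float = 1e-10):
    """EM for the unstructured multivariate normal under arbitrary missingness."""
    p = data.n_vars
    mu = np.where(np.isnan(data.means), 0.0, data.means)
    var = np.diag(data.cov).copy()
    var[~(var > 0)] = 1.0
    sigma = np.diag(var)
    for _ in range(max_iter):
        sum_m = np.zeros(p)
        sum_s = np.zeros((p, p))
        for g in data.pattern_groups:
            o = g.indices
            miss = np.setdiff1d(np.arange(p), o)
            m_full = np.empty(p)
            v_full = np.zeros((p, p))
            c_full = np.zeros((p, p))
            if len(miss):
                soo = sigma[np.ix_(o, o)]
                a = np.linalg.solve(soo, sigma[np.ix_(o, miss)]).T  # miss x obs
                m_full[o] = g.means
                m_full[miss] = mu[miss] + a @ (g.means - mu[o])
                v_full[np.ix_(o, o)] = g.cov
                v_full[np.ix_(miss, o)] = a @ g.cov
                v_full[np.ix_(o, miss)] = v_full[np.ix_(miss, o)].T
                v_full[np.ix_(miss, miss)] = a @ g.cov @ a.T
                c_full[np.ix_(miss, miss)] = sigma[np.ix_(miss, miss)] - a @ sigma[
                    np.ix_(o, miss)
                ]
            else:
                m_full[:] = g.means
                v_full[np.ix_(o, o)] = g.cov
            w = g.n / data.n
            sum_m += w * m_full
            sum_s += w * (v_full + np.outer(m_full, m_full) + c_full)
        new_mu = sum_m
        new_sigma = sum_s - np.outer(new_mu, new_mu)
        new_sigma = (new_sigma + new_sigma.T) / 2.0
        delta = max(
            np.max(np.abs(new_mu - mu)), np.max(np.abs(new_sigma - sigma))
        )
        mu, sigma = new_mu, new_sigma
        if delta < tol:
            break
    return mu, sigma


def _baseline_fit(data: MomentData, method: str):
    """Independence model (free means and variances, zero covariances)."""
    p = data.n_vars
    mu = np.empty(p)
    var = np.empty(p)
    for j in range(p):
        vals, ns = [], []
        for g in data.pattern_groups:
            pos = np.flatnonzero(g.indices == j)
            if len(pos):
                k = pos[0]
                vals.append((g.means[k], g.cov[k, k], g.n))
        n_obs = sum(v[2] for v in vals)
        m = sum(v[0] * v[2] for v in vals) / n_obs
        v2 = sum((v[1] + (v[0] - m) ** 2) * v[2] for v in vals) / n_obs
        mu[j], var[j] = m, max(v2, 1e-12)
    value = _fit_value(data, mu, np.diag(var), method)
    n_moments = p + p * (p + 1) // 2
    df_base = n_moments - 2 * p
    return value, df_base


# ---------------------------------------------------------------------------
# gradient machinery
# ---------------------------------------------------------------------------


def _moment_weights(data: MomentData, mu, sigma, method: str):
    """dF/dSigma (= W) and dF/dmu (= v), full stacked dimension."""
    p = data.n_vars
    w_full = np.zeros((p, p))
    v_full = np.zeros(p)
    groups = (
        data.pattern_groups
        if method == "fiml"
        else [PatternGroup(np.arange(p), data.n, data.means, data.cov)]
    )
    for g in groups:
        sub = sigma[np.ix_(g.indices, g.indices)]
        _, _, inv = _chol_pieces(sub)
        d = g.means - mu[g.indices]
        inv_d = inv @ d
        w = inv @ (sub - g.cov - np.outer(d, d)) @ inv
        weight = g.n / data.n
        w_full[np.ix_(g.indices, g.indices)] += weight * w
        v_full[g.indices] += weight * (-2.0 * inv_d)
    return w_full, v_full


def _mu_positions(model):
    """Stacked-mean positions touched by each mean-like family (cached).

    Returns a dict family -> (indicator index -> list of stacked positions).
    These parameters enter the mean linearly and never touch Sigma, so
    their structure derivatives are exact without finite differences.
    """
    cached = getattr(model, "_mu_pos_cache", None)
    if cached is not None:
        return cached
    kind = model.spec.kind
    out = {}
    if kind == "ts":
        n_y = model.n_stacked // 2
        out["intercept"] = {i: [n_y + i] for i in range(n_y)}
        out["star_mean"] = {i: [i] for i in range(n_y)}
    elif kind == "cross":
        p = model.n_stacked
        out["mean"] = {i: [i] for i in range(p)}
    elif kind == "panel":
        presence = model._template["_presence"].astype(bool)
        n_y, n_t = presence.shape
        keep = np.concatenate([presence[:, w] for w in range(n_t)])
        pos = -np.ones(len(keep), dtype=int)
        pos[np.flatnonzero(keep)] = np.arange(int(keep.sum()))
        out["intercept"] = {
            i: [int(pos[w * n_y + i]) for w in range(n_t) if keep[w * n_y + i]]
            for i in range(n_y)
        }
    model._mu_pos_cache = out
    return out


def _structure_jacobian_apply(model, values, w_full, v_full):
    """g_j = <W, dSigma/dv_j> + v . dmu/dv_j.

    Mean-only parameters and the saturated Cholesky block have exact
    derivatives; everything else uses central differences on the
    parameter -> (mu, Sigma) map.
    """
    mu_pos = _mu_positions(model)
    free = [p for p in model.params if p.free]
    star_l = None
    star_wl = None
    g = np.empty(len(values))
    for j, (p, v) in enumerate(zip(free, values)):
        if p.family in mu_pos:
            i = p.positions[0][1][0]
            g[j] = float(sum(v_full[pos] for pos in mu_pos[p.family][i]))
            continue
        if p.family == "star_cov":
            # Sigma* = L L'; d/dL_ij contracts to 2 (W* L)_ij
            if star_wl is None:
                mats = model.matrices(values)
                star_l = np.tril(mats["star_chol"])
                n_y = star_l.shape[0]
                star_wl = 2.0 * (w_full[:n_y, :n_y] @ star_l)
            i, k = p.positions[0][1]
            g[j] = float(star_wl[i, k])
            continue
        h = _FD_STEP * max(1.0, abs(v))
        up = values.copy()
        up[j] = v + h
        dn = values.copy()
        dn[j] = v - h
        mu_u, s_u = model.moments(up)
        mu_d, s_d = model.moments(dn)
        dmu = (mu_u - mu_d) / (2 * h)
        dsig = (s_u - s_d) / (2 * h)
        g[j] = float(np.sum(w_full * dsig) + v_full @ dmu)
    return g


def _gradient_natural(model, data, values, method):
    mu, sigma = model.moments(values)
    w_full, v_full = _moment_weights(data, mu, sigma, method)
    return _structure_jacobian_apply(model, values, w_full, v_full)


def _structure_jacobian(model, values):
    """Jacobian of the parameter -> (mu, Sigma) map (exact where possible)."""
    mu0, sig0 = model.moments(values)
    k, p = len(values), len(mu0)
    j_mu = np.zeros((k, p))
    j_sig = np.zeros((k, p, p))
    mu_pos = _mu_positions(model)
    free = [q for q in model.params if q.free]
    star_l = None
    for j, (q, v) in enumerate(zip(free, values)):
        if q.family in mu_pos:
            i = q.positions[0][1][0]
            for pos in mu_pos[q.family][i]:
                j_mu[j, pos] = 1.0
            continue
        if q.family == "star_cov":
            if star_l is None:
                star_l = np.tril(model.matrices(values)["star_chol"])
            i, c = q.positions[0][1]
            n_y = star_l.shape[0]
            d = np.zeros((n_y, n_y))
            d[i, :] = star_l[:, c]
            d[:, i] += star_l[:, c]
            j_sig[j, :n_y, :n_y] = d
            continue
        h = _FD_STEP * max(1.0, abs(v))
        up = values.copy()
        up[j] = v + h
        dn = values.copy()
        dn[j] = v - h
        mu_u, s_u = model.moments(up)
        mu_d, s_d = model.moments(dn)
        j_mu[j] = (mu_u - mu_d) / (2 * h)
        j_sig[j] = (s_u - s_d) / (2 * h)
    return mu0, sig0, j_mu, j_sig


def expected_information_hessian(model, data, values, method):
    """Expected (Fisher) Hessian of F with respect to natural parameters.

    ``H_ij = sum_g w_g [ tr(Sg^-1 dSig_i Sg^-1 dSig_j) + 2 dmu_i' Sg^-1 dmu_j ]``
    evaluated at the current estimates; multiplied by n/2 this is the
    expected information.  Exact in the moment derivatives up to the FD
    structure Jacobian, and positive semidefinite by construction.
    """
    mu0, sig0, j_mu, j_sig = _structure_jacobian(model, values)
    k = len(values)
    h = np.zeros((k, k))
    groups = (
        data.pattern_groups
        if method == "fiml"
        else [PatternGroup(np.arange(data.n_vars), data.n, data.means, data.cov)]
    )
    for g in groups:
        idx = g.indices
        _, _, inv = _chol_pieces(sig0[np.ix_(idx, idx)])
        w = g.n / data.n
        t = np.einsum("ab,jbc->jac", inv, j_sig[:, idx[:, None], idx[None, :]])
        u = j_mu[:, idx] @ inv
        h += w * (
            np.einsum("iab,jba->ij", t, t) + 2.0 * u @ j_mu[:, idx].T
        )
    return (h + h.T) / 2.0


def _chain_factors(model) -> np.ndarray:
    """d(natural)/d(theta) for the elementwise transforms."""
    out = []
    for p in model.params:
        if not p.free:
            continue
        if p.transform == "log":
            out.append(p.value)
        elif p.transform == "atanh":
            out.append(1.0 - p.value**2)
        else:
            out.append(1.0)
    return np.array(out)


def _hessian_natural(model, data, values, method, step: float = 1e-5):
    """Central-difference Hessian of F with respect to natural parameters."""
    k = len(values)
    h = np.empty((k, k))
    for j in range(k):
        hj = step * max(1.0, abs(values[j]))
        up = values.copy()
        up[j] += hj
        dn = values.copy()
        dn[j] -= hj
        g_u = _gradient_natural(model, data, up, method)
        g_d = _gradient_natural(model, data, dn, method)
        h[j] = (g_u - g_d) / (2 * hj)
    return (h + h.T) / 2.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, discrepancy, likelihood quantities and fit indices."""

    model: CompiledModel
    data: MomentData
    method: str
    fvalue: float
    loglik: float
    n_free: int
    df: int
    converged: bool
    reason: str = ""
    chi_square: float = None
    p_value: float = None
    aic: float = None
    bic: float = None
    rmsea: float = None
    rmsea_ci: tuple = None
    indices: dict = field(default_factory=dict)
    se: dict = None
    pvalues: dict = None
    se_flag: str = ""

    @property
    def estimates(self) -> dict:
        return {p.name: p.value for p in self.model.params if p.free}

    def summary(self) -> str:
        lines = [
            f"lvgvar fit ({self.model.spec.kind}, {self.method.upper()}), "
            f"n = {self.data.n}",
            f"converged: {self.converged} {('[' + self.reason + ']') if self.reason else ''}",
            f"F = {self.fvalue:.6f}  logL = {self.loglik:.3f}",
            f"chi2({self.df}) = {self.chi_square:.2f}  p = {self.p_value:.4g}"
            if self.chi_square is not None
            else "chi2: not computed",
            f"RMSEA = {self.rmsea:.3f}"
            + (
                f" (95% CI {self.rmsea_ci[0]:.3f}-{self.rmsea_ci[1]:.3f})"
                if self.rmsea_ci is not None
                else ""
            )
            if self.rmsea is not None
            else "",
            f"AIC = {self.aic:.2f}  BIC = {self.bic:.2f}",
        ]
        if self.indices:
            lines.append(
                "  ".join(f"{k} = {v:.3f}" for k, v in self.indices.items())
            )
        return "\n".join(s for s in lines if s)

    def to_dict(self) -> dict:
        return {
            "kind": self.model.spec.kind,
            "method": self.method,
            "n": int(self.data.n),
            "converged": bool(self.converged),
            "reason": self.reason,
            "fvalue": self.fvalue,
            "loglik": self.loglik,
            "chi_square": self.chi_square,
            "df": int(self.df),
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci) if self.rmsea_ci else None,
            "aic": self.aic,
            "bic": self.bic,
            "indices": self.indices,
            "estimates": self.estimates,
        }


def _default_starts(model: CompiledModel, data: MomentData) -> None:
    """Heuristic, deterministic starting values from sample moments."""
    var = np.diag(data.cov).copy()
    var[~(var > 0) | np.isnan(var)] = 1.0
    means = np.where(np.isnan(data.means), 0.0, data.means)
    labels = model.var_labels
    kind = model.spec.kind
    n_y = len(labels) // 2 if kind == "ts" else None
    for p in model.params:
        if not p.free:
            continue
        key, idx = p.positions[0]
        if p.family == "intercept":
            i = idx[0]
            col = n_y + i if kind == "ts" else i
            p.value = float(means[col])
        elif p.family == "mean":
            p.value = float(means[idx[0]])
        elif p.family == "star_mean":
            p.value = float(means[idx[0]])
        elif p.family == "star_cov":
            i, j = idx
            p.value = float(np.sqrt(var[i])) if i == j else 0.0
        elif p.family == "residual":
            i = idx[0]
            col = n_y + i if kind == "ts" else i
            p.value = float(np.sqrt(0.4 * var[col]))
        elif p.family == "residual_between":
            p.value = float(np.sqrt(0.2 * var[idx[0]]))
        elif p.family in ("scaling", "scaling_between"):
            scale = float(np.sqrt(np.mean(var)))
            p.value = 0.5 * scale if p.family == "scaling_between" else 0.6 * scale
        # loadings, temporal, partials keep their spec-level starts


def fit(
    spec_or_model,
    data: MomentData,
    method: str = "ml",
    start_from_data: bool = True,
    warm_start=None,
    compute_indices: bool = True,
    max_iter: int = 2000,
) -> FitResult:
    """Fit a model spec to sample moments; returns a :class:`FitResult`.

    Numerical failures (non-PD implied covariance at the solution,
    optimizer breakdown) are reported through ``converged``/``reason``
    rather than raised, so simulation studies can tally success rates.
    """
    if method not in ("ml", "fiml"):
        raise ValueError("method must be 'ml' or 'fiml'")
    model = (
        spec_or_model.copy()
        if isinstance(spec_or_model, CompiledModel)
        else compile_spec(spec_or_model)
    )
    if list(data.labels) != list(model.var_labels):
        raise DataError(
            "data labels do not match the model's stacked variable layout"
        )
    if method == "ml" and not data.complete:
        raise DataError("ML estimation requires complete data; use FIML")
    if warm_start is not None:
        model.set_free_vector(warm_start)
    elif start_from_data:
        _default_starts(model, data)

    free_params = model.free_params
    transforms = [p.transform for p in free_params]

    def to_natural(theta):
        return np.array(
            [
                np.exp(t) if tr == "log" else np.tanh(t) if tr == "atanh" else t
                for t, tr in zip(theta, transforms)
            ]
        )

    def fun(theta):
        values = to_natural(theta)
        try:
            mu, sigma = model.moments(values)
            f = _fit_value(data, mu, sigma, method)
            w_full, v_full = _moment_weights(data, mu, sigma, method)
            g_nat = _structure_jacobian_apply(model, values, w_full, v_full)
        except (NetworkError, NotPositiveDefiniteError, np.linalg.LinAlgError):
            return _PENALTY, np.zeros_like(theta)
        chain = np.array(
            [
                v if tr == "log" else (1.0 - v**2) if tr == "atanh" else 1.0
                for v, tr in zip(values, transforms)
            ]
        )
        return f, g_nat * chain

    theta0 = model.theta()
    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    values = to_natural(res.x)
    model.set_free_vector(values)
    converged, reason = True, ""
    try:
        mu, sigma = model.moments()
        fvalue = _fit_value(data, mu, sigma, method)
        if fvalue >= _PENALTY / 2:
            converged, reason = False, "penalized solution (non-PD or unstable)"
    except (NetworkError, NotPositiveDefiniteError, np.linalg.LinAlgError) as exc:
        fvalue = float(res.fun)
        converged, reason = False, type(exc).__name__
    if not res.success and res.status != 1:  # status 1 = maxiter, still usable
        if not (np.isfinite(res.fun) and res.fun < _PENALTY / 2):
            converged, reason = False, str(res.message)

    n = data.n
    const = _loglik_constant(data, method)
    loglik = -0.5 * n * (fvalue + const)
    k = len(free_params)
    result = FitResult(
        model=model,
        data=data,
        method=method,
        fvalue=fvalue,
        loglik=loglik,
        n_free=k,
        df=degrees_of_freedom(model),
        converged=converged,
        reason=reason,
    )
    if compute_indices and converged:
        try:
            chi_square_and_indices(result)
        except (NetworkError, DataError, np.linalg.LinAlgError):
            result.converged = False
            result.reason = "fit-index computation failed"
    return result


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def standard_errors(result: FitResult, information: str = "expected") -> dict:
    """SEs and two-sided normal p-values from the inverse information.

    The information is the Hessian of ``(n/2) F`` at the optimum with
    respect to the *natural* (model-scale) parameters, so SEs apply
    directly to loadings, partials, temporal coefficients.  The default
    uses the expected (Fisher) information; ``information="observed"``
    switches to a fully numerical second-derivative matrix.
    """
    if result.se is not None:
        return result.se
    if not result.converged:
        raise ValueError("standard errors require a converged fit")
    model, data = result.model, result.data
    values = model.free_vector()
    if information == "observed":
        h = _hessian_natural(model, data, values, result.method)
    else:
        h = expected_information_hessian(model, data, values, result.method)
    info = (data.n / 2.0) * h
    flag = ""
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov).copy()
        if np.any(diag <= 0):
            flag = "non-positive-definite information"
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        diag = np.diag(cov).copy()
        flag = "singular information (pseudo-inverse)"
    se = np.sqrt(np.where(diag > 0, diag, np.nan))
    names = model.free_names
    result.se = dict(zip(names, se))
    z = values / se
    result.pvalues = {
        nm: 2.0 * float(stats.norm.sf(abs(zz))) if np.isfinite(zz) else np.nan
        for nm, zz in zip(names, z)
    }
    result.se_flag = flag
    return result.se


def _rmsea_ci(chi2_val, df, n, level=0.95):
    """Noncentrality-based RMSEA confidence interval via root finding."""
    lo_p, hi_p = (1 - level) / 2, 1 - (1 - level) / 2

    def ncp_for(prob):
        # find lambda with ncx2.cdf(chi2_val; df, lambda) == prob
        f = lambda lam: stats.ncx2.cdf(chi2_val, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2_val, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_hi = ncp_for(lo_p)  # upper bound of lambda
    lam_lo = ncp_for(hi_p)
    return (
        float(np.sqrt(max(lam_lo, 0.0) / (df * n))),
        float(np.sqrt(max(lam_hi, 0.0) / (df * n))),
    )


def chi_square_and_indices(result: FitResult) -> FitResult:
    """Fill chi-square, RMSEA (with 95% CI), AIC/BIC and incremental indices."""
    data, method, n = result.data, result.method, result.data.n
    f_sat = saturated_fit_value(data, method)
    chi2_val = max(n * (result.fvalue - f_sat), 0.0)
    df = result.df
    result.chi_square = chi2_val
    result.p_value = float(stats.chi2.sf(chi2_val, df)) if df > 0 else 1.0
    k = result.n_free
    neg2ll = -2.0 * result.loglik
    result.aic = neg2ll + 2 * k
    result.bic = neg2ll + k * np.log(n)
    if df > 0:
        result.rmsea = float(np.sqrt(max(chi2_val - df, 0.0) / (df * n)))
        result.rmsea_ci = _rmsea_ci(chi2_val, df, n)
    else:
        result.rmsea = 0.0 if chi2_val <= 1e-8 else None
        result.rmsea_ci = None
    # incremental indices against the independence baseline
    if df > 0:
        f_base, df_base = _baseline_fit(data, method)
        chi2_b = max(n * (f_base - f_sat), 0.0)
        if chi2_b > 0 and df_base > 0:
            r_m = chi2_val / df
            r_b = chi2_b / df_base
            idx = {}
            idx["NFI"] = (chi2_b - chi2_val) / chi2_b
            idx["PNFI"] = (df / df_base) * idx["NFI"]
            idx["TLI"] = (r_b - r_m) / (r_b - 1.0) if r_b != 1.0 else np.nan
            idx["NNFI"] = idx["TLI"]
            idx["RFI"] = (r_b - r_m) / r_b
            idx["IFI"] = (chi2_b - chi2_val) / (chi2_b - df)
            denom = chi2_b - df_base
            idx["RNI"] = ((chi2_b - df_base) - (chi2_val - df)) / denom
            num_cfi = max(chi2_val - df, 0.0)
            den_cfi = max(chi2_b - df_base, num_cfi, 1e-12)
            idx["CFI"] = 1.0 - num_cfi / den_cfi
            for nm in ("CFI", "TLI", "NNFI"):
                if np.isfinite(idx[nm]):
                    idx[nm] = float(np.clip(idx[nm], 0.0, 1.0))
            result.indices = {nm: float(v) for nm, v in idx.items()}
    return result


def compare(fit_nested: FitResult, fit_full: FitResult) -> dict:
    """Likelihood-ratio comparison of two nested fits on the same data."""
    if fit_nested.data is not fit_full.data and not (
        fit_nested.data.n == fit_full.data.n
        and np.allclose(
            fit_nested.data.means, fit_full.data.means, equal_nan=True
        )
    ):
        raise ValueError("fits must be based on the same data")
    if fit_nested.n_free > fit_full.n_free:
        raise ValueError("first argument must be the nested (smaller) model")
    n = fit_full.data.n
    d_chi2 = n * (fit_nested.fvalue - fit_full.fvalue)
    d_df = fit_full.n_free - fit_nested.n_free
    p = float(stats.chi2.sf(max(d_chi2, 0.0), d_df)) if d_df > 0 else 1.0
    return {
        "delta_chi_square": float(d_chi2),
        "delta_df": int(d_df),
        "p_value": p,
        "delta_aic": float(fit_nested.aic - fit_full.aic)
        if fit_nested.aic is not None and fit_full.aic is not None
        else None,
        "delta_bic": float(fit_nested.bic - fit_full.bic)
        if fit_nested.bic is not None and fit_full.bic is not None
        else None,
    }


def score_information(result: FitResult, candidate_names):
    """Gradient and Hessian of F over (free + candidate) natural parameters.

    Candidates are currently-fixed parameters evaluated at their fixed
    values; used by the score-test modification indices.
    """
    model = result.model.copy()
    for name in candidate_names:
        p = model.get(name)
        model = model.with_freed(name, p.value)
    values = model.free_vector()
    g = _gradient_natural(model, result.data, values, result.method)
    h = expected_information_hessian(model, result.data, values, result.method)
    return model.free_names, g, h
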