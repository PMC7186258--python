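"""Sparse-structure search over network parameters.

The search pipeline mirrors the stepwise workflow used for the empirical
analyses: (1) fit the fully connected model, (2) fix to zero all network
edges not significant at the chosen alpha (optionally with Bonferroni,
Holm or Benjamini-Hochberg FDR adjustment, applied per network matrix)
and refit, (3) stepwise single-edge search that frees zero edges with a
significant modification index and fixes non-significant free edges,
accepting the single change with the best BIC per iteration until BIC no
longer improves.  Strategy variants: ``prune`` (stop after step 2),
``stepup`` (additions only), ``modelsearch`` (full neighborhood).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimation import (
    FitResult,
    fit,
    score_information,
    standard_errors,
)

__all__ = [
    "SearchError",
    "SearchStep",
    "SearchTrace",
    "prune",
    "modification_indices",
    "stepup",
    "modelsearch",
    "run_pipeline",
]

_ADJUSTMENTS = {
    "none": None,
    "bonferroni": "bonferroni",
    "holm": "holm",
    "fdr": "fdr_bh",
}


class SearchError(RuntimeError):
    """Model search could not proceed (e.g. missing standard errors)."""


@dataclass
class SearchStep:
    action: str  # 'prune' | 'add' | 'remove'
    parameter: str
    bic_before: float
    bic_after: float
    statistic: float  # p-value (prune/remove) or modification index (add)


@dataclass
class SearchTrace:
    settings: dict
    steps: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([s.__dict__ for s in self.steps])


def adjusted_pvalues(pvals, adjustment: str):
    """Multiplicity-adjusted p-values for one family of edges."""
    pvals = np.asarray(pvals, dtype=float)
    if adjustment not in _ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if adjustment == "none" or len(pvals) == 0:
        return pvals
    return multipletests(pvals, method=_ADJUSTMENTS[adjustment])[1]


def prune(result: FitResult, alpha: float = 0.01, adjustment: str = "none"):
    """Fix non-significant searchable edges to zero; returns a spec to refit.

    The multiplicity-adjustment family is one network matrix (temporal,
    contemporaneous, between are adjusted separately).
    """
    standard_errors(result)
    if result.pvalues is None:
        raise SearchError("pruning requires standard errors and p-values")
    model = result.model
    new = model.copy()
    dropped = []
    for family in model.search_families:
        names = [p.name for p in model.searchable(family) if p.free]
        if not names:
            continue
        pvals = []
        for nm in names:
            pv = result.pvalues.get(nm, np.nan)
            if not np.isfinite(pv):
                raise SearchError(f"missing p-value for searchable edge {nm}")
            pvals.append(pv)
        adj = adjusted_pvalues(pvals, adjustment)
        for nm, pv in zip(names, adj):
            if pv > alpha:
                new = new.with_fixed(nm, 0.0)
                dropped.append((nm, float(pv)))
    return new, dropped


def modification_indices(result: FitResult) -> dict:
    """Score-test (Lagrange multiplier) indices for zero-fixed edges.

    Each index approximates the chi-square decrease from freeing one edge:
    ``MI = (n/2) g_c^2 / s_cc`` with ``g_c`` the fit-function gradient at
    the constraint and ``s_cc`` the curvature after profiling out the free
    parameters (Schur complement of the expected information).
    """
    model = result.model
    candidates = [p.name for p in model.searchable() if not p.free]
    if not candidates:
        return {}
    names, g, h = score_information(result, candidates)
    pos = {nm: i for i, nm in enumerate(names)}
    free_idx = [i for i, nm in enumerate(names) if nm not in candidates]
    n = result.data.n
    out = {}
    h_ff = h[np.ix_(free_idx, free_idx)]
    for nm in candidates:
        c = pos[nm]
        h_fc = h[free_idx, c]
        try:
            sol = np.linalg.solve(h_ff, h_fc)
            s_cc = h[c, c] - h_fc @ sol
        except np.linalg.LinAlgError:
            out[nm] = np.nan
            continue
        out[nm] = float((n / 2.0) * g[c] ** 2 / s_cc) if s_cc > 1e-12 else np.nan
    return out


def _refit(model, result, **kw):
    """Warm-started refit of an edited structure on the same data."""
    return fit(
        model,
        result.data,
        method=result.method,
        warm_start=model.free_vector(),
        start_from_data=False,
        **kw,
    )


def stepup(result: FitResult, alpha: float = 0.05, trace: SearchTrace = None):
    """Free the strongest-MI edge while BIC improves; returns the best fit."""
    current = result
    while True:
        mis = modification_indices(current)
        sig = {
            nm: mi
            for nm, mi in mis.items()
            if np.isfinite(mi) and stats.chi2.sf(mi, 1) < alpha
        }
        if not sig:
            return current
        best = max(sorted(sig), key=lambda nm: sig[nm])
        candidate = current.model.with_freed(best, 0.0)
        new_fit = _refit(candidate, current)
        if not new_fit.converged or new_fit.bic >= current.bic:
            return current
        if trace is not None:
            trace.steps.append(
                SearchStep("add", best, current.bic, new_fit.bic, sig[best])
            )
        current = new_fit


def modelsearch(result: FitResult, alpha: float = 0.01, trace: SearchTrace = None):
    """BIC-optimizing stepwise search over single-edge changes.

    Per iteration the candidate set contains (a) zero edges whose
    modification index is significant at ``alpha`` and (b) free edges that
    are not significant at ``alpha``; each candidate model is refit and the
    single change with the largest BIC improvement is accepted.  Removal is
    preferred on ties, then lexicographic parameter order.  Terminates when
    no candidate improves BIC, so the accepted-BIC sequence is strictly
    decreasing.
    """
    current = result
    while True:
        candidates = []  # (kind_rank, name, action, statistic)
        standard_errors(current)
        for p in current.model.searchable():
            if p.free:
                pv = current.pvalues.get(p.name, np.nan)
                if np.isfinite(pv) and pv > alpha:
                    candidates.append((0, p.name, "remove", pv))
        mis = modification_indices(current)
        for nm, mi in mis.items():
            if np.isfinite(mi) and stats.chi2.sf(mi, 1) < alpha:
                candidates.append((1, nm, "add", mi))
        if not candidates:
            return current
        best_fit, best_key, best_step = None, None, None
        for rank, nm, action, stat in sorted(candidates):
            if action == "remove":
                cand_model = current.model.with_fixed(nm, 0.0)
            else:
                cand_model = current.model.with_freed(nm, 0.0)
            cand_fit = _refit(cand_model, current)
            if not cand_fit.converged:
                continue
            key = (cand_fit.bic, rank, nm)
            if best_key is None or key < best_key:
                best_key, best_fit = key, cand_fit
                best_step = SearchStep(action, nm, current.bic, cand_fit.bic, stat)
        if best_fit is None or best_fit.bic >= current.bic:
            return current
        if trace is not None:
            trace.steps.append(best_step)
        current = best_fit


def run_pipeline(
    spec_or_model,
    data,
    method: str = "ml",
    alpha: float = 0.01,
    adjustment: str = "none",
    strategy: str = "modelsearch",
):
    """Full search pipeline: saturated fit, prune + refit, stepwise search.

    Returns ``(final_fit, trace)``; a non-converged initial fit is returned
    as-is with an empty trace so callers can tally failures.
    """
    if strategy not in ("prune", "stepup", "modelsearch"):
        raise ValueError(f"unknown strategy {strategy!r}")
    trace = SearchTrace(
        settings={"alpha": alpha, "adjustment": adjustment, "strategy": strategy}
    )
    full = fit(spec_or_model, data, method=method)
    if not full.converged:
        return full, trace
    pruned_model, dropped = prune(full, alpha=alpha, adjustment=adjustment)
    current = full
    if dropped:
        pruned_fit = _refit(pruned_model, full)
        if not pruned_fit.converged:
            return pruned_fit, trace
        for nm, pv in dropped:
            trace.steps.append(SearchStep("prune", nm, full.bic, pruned_fit.bic, pv))
        current = pruned_fit
    if strategy == "stepup":
        current = stepup(current, alpha=alpha, trace=trace)
    elif strategy == "modelsearch":
        current = modelsearch(current, alpha=alpha, trace=trace)
    return current, trace


def run_variant_grid(
    spec_or_model,
    data,
    method: str = "ml",
    strategies=("prune", "stepup", "modelsearch"),
    adjustments=("none", "bonferroni", "holm", "fdr"),
    alphas=(0.01, 0.05),
) -> dict:
    """Run every (strategy, adjustment, alpha) variant on one dataset.

    Work is shared across variants: the fully connected model is fit once,
    each (adjustment, alpha) pair prunes and refits once, and the search
    strategies continue from the shared pruned fit.  Returns a dict mapping
    (strategy, adjustment, alpha) to the final :class:`FitResult` (or to
    the failed fit when estimation broke down).
    """
    results = {}
    full = fit(spec_or_model, data, method=method)
    if not full.converged:
        for strategy in strategies:
            for adjustment in adjustments:
                for alpha in alphas:
                    results[(strategy, adjustment, alpha)] = full
        return results
    standard_errors(full)
    for adjustment in adjustments:
        for alpha in alphas:
            pruned_model, dropped = prune(full, alpha=alpha, adjustment=adjustment)
            current = full
            if dropped:
                pruned_fit = _refit(pruned_model, full)
                current = pruned_fit
            for strategy in strategies:
                if not current.converged:
                    results[(strategy, adjustment, alpha)] = current
                    continue
                if strategy == "prune":
                    final = current
                elif strategy == "stepup":
                    final = stepup(current, alpha=alpha)
                else:
                    final = modelsearch(current, alpha=alpha)
                results[(strategy, adjustment, alpha)] = final
    return results
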