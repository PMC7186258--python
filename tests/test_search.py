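"""Significance pruning, modification indices, stepwise search."""

import numpy as np
import pandas as pd
import pytest

from lvgvar.estimation import MomentData, fit, standard_errors
from lvgvar.networks import GaussianNetwork, network_to_covariance
from lvgvar.search import (
    SearchTrace,
    adjusted_pvalues,
    modelsearch,
    modification_indices,
    prune,
    run_pipeline,
    stepup,
)
from lvgvar.specs import CrossSectionalSpec, compile_spec


def _cross_data(rng, omega, n, delta=None, labels=None):
    p = omega.shape[0]
    labels = labels or [chr(ord("a") + i) for i in range(p)]
    sigma = network_to_covariance(GaussianNetwork(omega=omega, delta=delta))
    frame = pd.DataFrame(
        rng.multivariate_normal(np.zeros(p), sigma, size=n), columns=labels
    )
    return MomentData.from_dataframe(frame), labels


class TestAdjustments:
    def test_holm_stepdown_by_hand(self):
        # 0.03 * 2 = 0.06 > 0.05 stops the sequence after the first rejection
        adj = adjusted_pvalues([0.001, 0.03, 0.04], "holm")
        survives = adj <= 0.05
        assert survives.tolist() == [True, False, False]

    def test_fdr_benjamini_hochberg_by_hand(self):
        # BH thresholds at alpha=0.05 for m=3: 0.0167, 0.0333, 0.05
        adj = adjusted_pvalues([0.01, 0.02, 0.20], "fdr")
        survives = adj <= 0.05
        assert survives.tolist() == [True, True, False]

    def test_none_is_identity(self):
        p = [0.2, 0.01]
        assert np.allclose(adjusted_pvalues(p, "none"), p)

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            adjusted_pvalues([0.1], "sidak")


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(42)
    omega = np.zeros((4, 4))
    omega[0, 1] = omega[1, 0] = 0.35
    omega[2, 3] = omega[3, 2] = -0.30
    data, labels = _cross_data(rng, omega, n=800)
    res = fit(CrossSectionalSpec(labels=labels), data, method="ml")
    standard_errors(res)
    return res


class TestPrune:
    def test_all_significant_edges_survive(self, fitted):
        new, dropped = prune(fitted, alpha=0.999999, adjustment="none")
        assert dropped == []
        assert sum(p.free for p in new.params) == sum(
            p.free for p in fitted.model.params
        )

    def test_pruned_edges_are_fixed_at_zero(self, fitted):
        new, dropped = prune(fitted, alpha=0.01, adjustment="none")
        assert dropped
        for name, _ in dropped:
            p = new.get(name)
            assert not p.free and p.value == 0.0

    def test_non_network_parameters_untouched(self, fitted):
        new, _ = prune(fitted, alpha=0.0001, adjustment="bonferroni")
        for p in new.params:
            if not p.searchable:
                assert p.free == fitted.model.get(p.name).free

    def test_none_never_stricter_than_bonferroni(self, fitted):
        plain, _ = prune(fitted, alpha=0.05, adjustment="none")
        bonf, _ = prune(fitted, alpha=0.05, adjustment="bonferroni")
        kept_plain = {p.name for p in plain.params if p.searchable and p.free}
        kept_bonf = {p.name for p in bonf.params if p.searchable and p.free}
        assert kept_bonf <= kept_plain


class TestModificationIndices:
    def test_saturated_network_has_no_entries(self):
        rng = np.random.default_rng(7)
        omega = np.zeros((3, 3))
        data, labels = _cross_data(rng, omega, n=300)
        res = fit(CrossSectionalSpec(labels=labels), data, method="ml")
        assert modification_indices(res) == {}

    def test_mi_approximates_chi_square_drop_on_refit(self):
        # freeing the top-MI edge should drop chi-square by about the MI
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            omega = np.zeros((4, 4))
            omega[0, 1] = omega[1, 0] = rng.uniform(0.25, 0.4)
            omega[1, 2] = omega[2, 1] = rng.uniform(0.2, 0.35)
            data, labels = _cross_data(rng, omega, n=1500)
            spec = CrossSectionalSpec(
                labels=labels, omega_free=np.zeros((4, 4), dtype=bool)
            )
            restricted = fit(spec, data, method="ml")
            mis = modification_indices(restricted)
            top = max(mis, key=lambda nm: mis[nm])
            freed = fit(
                restricted.model.with_freed(top, 0.0), data, method="ml",
                start_from_data=False,
            )
            d_chi2 = data.n * (restricted.fvalue - freed.fvalue)
            if abs(mis[top] - d_chi2) <= 0.25 * d_chi2:
                hits += 1
        assert hits >= 5

    def test_true_zero_edge_mi_calibrates_to_chi2_1(self):
        # the MI of a truly absent edge is asymptotically chi-square(1): mean 1
        mis = []
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            omega = np.zeros((3, 3))
            omega[0, 1] = omega[1, 0] = 0.3
            data, labels = _cross_data(rng, omega, n=800)
            free = np.zeros((3, 3), dtype=bool)
            free[0, 1] = free[1, 0] = True
            spec = CrossSectionalSpec(labels=labels, omega_free=free)
            res = fit(spec, data, method="ml")
            mis.append(modification_indices(res)["omega[c,b]"])
        assert 0.5 < np.mean(mis) < 2.0


class TestStepup:
    def test_no_constrained_edges_returns_input(self):
        rng = np.random.default_rng(3)
        data, labels = _cross_data(rng, np.zeros((3, 3)), n=300)
        res = fit(CrossSectionalSpec(labels=labels), data, method="ml")
        assert stepup(res, alpha=0.05) is res

    def test_single_dominant_edge_is_added(self):
        rng = np.random.default_rng(5)
        omega = np.zeros((4, 4))
        omega[0, 1] = omega[1, 0] = 0.5
        data, labels = _cross_data(rng, omega, n=3000)
        spec = CrossSectionalSpec(
            labels=labels, omega_free=np.zeros((4, 4), dtype=bool)
        )
        res = fit(spec, data, method="ml")
        out = stepup(res, alpha=0.01)
        freed = [
            p.name for p in out.model.params if p.searchable and p.free
        ]
        assert freed == ["omega[b,a]"]

    def test_true_structure_start_rarely_grows(self, ts_truth, ts_blank):
        from lvgvar.io import timeseries_moments
        from lvgvar.simulate import simulate_ts

        added = 0
        for seed in (11, 12, 13):
            ds = simulate_ts(ts_truth, n_occasions=300, seed=seed)
            data = timeseries_moments(ds, method="ml")
            truth_spec = compile_spec(ts_truth)
            start = compile_spec(ts_blank)
            for p in truth_spec.params:
                if p.searchable and p.value == 0.0:
                    start = start.with_fixed(p.name, 0.0)
            res = fit(start, data, method="ml")
            out = stepup(res, alpha=0.01)
            added += out.n_free - res.n_free
        assert added <= 1  # on average no BIC-improving additions exist


class TestModelsearch:
    def test_locally_optimal_input_returned_unchanged(self):
        rng = np.random.default_rng(9)
        omega = np.zeros((3, 3))
        omega[0, 1] = omega[1, 0] = 0.5
        data, labels = _cross_data(rng, omega, n=4000)
        free = np.zeros((3, 3), dtype=bool)
        free[0, 1] = free[1, 0] = True
        res = fit(CrossSectionalSpec(labels=labels, omega_free=free), data)
        out = modelsearch(res, alpha=0.01)
        assert out.n_free == res.n_free

    def test_trace_bic_strictly_decreasing(self, ts_blank, ts_data):
        final, trace = run_pipeline(
            ts_blank, ts_data, method="ml", alpha=0.05,
            adjustment="none", strategy="modelsearch",
        )
        assert final.converged
        frame = trace.to_frame()
        search_steps = frame[frame.action != "prune"]
        if len(search_steps):
            assert (search_steps.bic_after.to_numpy()
                    < search_steps.bic_before.to_numpy()).all()
            assert (np.diff(search_steps.bic_after.to_numpy()) < 0).all()
        assert final.bic <= frame.bic_before.iloc[0] + 1e-9

    def test_recovers_generating_structure(self, ts_truth, ts_blank, ts_data):
        from lvgvar.simulate import edge_metrics

        final, _ = run_pipeline(
            ts_blank, ts_data, method="ml", alpha=0.01,
            adjustment="none", strategy="modelsearch",
        )
        m = edge_metrics(ts_truth, final)
        assert m.sensitivity > 0.5 and m.specificity > 0.5


class TestPipeline:
    def test_unknown_strategy_rejected(self, ts_blank, ts_data):
        with pytest.raises(ValueError):
            run_pipeline(ts_blank, ts_data, strategy="exhaustive")

    def test_variant_grid_is_expressible_without_code_changes(self):
        # the full 3 strategies x 4 adjustments x 2 alphas grid is pure settings
        from itertools import product

        from lvgvar.simulate import SimConfig, small_ts_model

        cfg = SimConfig(
            generating_spec=small_ts_model(), sample_sizes=[100], replicates=1
        )
        variants = list(product(cfg.strategies, cfg.adjustments, cfg.alphas))
        assert len(variants) == 24
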