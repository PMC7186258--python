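"""ML/FIML fit functions, optimization, standard errors, fit indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lvgvar.estimation import (
    DataError,
    MomentData,
    PatternGroup,
    chi_square_and_indices,
    compare,
    fiml_fit_value,
    fit,
    ml_fit_value,
    saturated_fit_value,
    standard_errors,
)
from lvgvar.networks import GaussianNetwork, network_to_covariance
from lvgvar.specs import CrossSectionalSpec, compile_spec, degrees_of_freedom

from conftest import random_network


def _mvn_frame(rng, mu, sigma, n, labels):
    return pd.DataFrame(rng.multivariate_normal(mu, sigma, size=n), columns=labels)


class TestMlFitValue:
    def test_identity_moments_give_dimension(self):
        p = 5
        data = MomentData.from_moments(np.zeros(p), np.eye(p), 100, list("abcde"))
        assert ml_fit_value(data, np.zeros(p), np.eye(p)) == pytest.approx(p)

    def test_saturated_minimum_is_p_plus_logdet(self, rng):
        sigma = network_to_covariance(random_network(rng, 3))
        mu = rng.normal(size=3)
        data = MomentData.from_moments(mu, sigma, 50, list("abc"))
        expected = 3 + np.linalg.slogdet(sigma)[1]
        assert ml_fit_value(data, mu, sigma) == pytest.approx(expected)
        assert saturated_fit_value(data) == pytest.approx(expected)

    def test_matches_density_sum_oracle(self, rng):
        # F equals -2/n * sum log N(z_c; mu, Sigma) minus the 2*pi constant
        p, n = 3, 50
        sigma_true = network_to_covariance(random_network(rng, p))
        x = rng.multivariate_normal(np.zeros(p), sigma_true, size=n)
        data = MomentData.from_dataframe(pd.DataFrame(x, columns=list("abc")))
        mu = np.array([0.1, -0.2, 0.3])
        sigma = network_to_covariance(random_network(rng, p))
        loglik = stats.multivariate_normal(mu, sigma).logpdf(x).sum()
        expected = -2.0 / n * loglik - p * np.log(2 * np.pi)
        assert ml_fit_value(data, mu, sigma) == pytest.approx(expected)


class TestFimlFitValue:
    def test_single_complete_pattern_equals_ml(self, rng):
        x = rng.normal(size=(40, 3))
        data = MomentData.from_dataframe(pd.DataFrame(x, columns=list("abc")))
        mu = np.zeros(3)
        sigma = np.eye(3) * 1.5
        assert fiml_fit_value(data, mu, sigma) == pytest.approx(
            ml_fit_value(data, mu, sigma)
        )

    def test_artificially_split_complete_patterns_equal_ml(self, rng):
        x = rng.normal(size=(60, 3))
        labels = list("abc")
        whole = MomentData.from_dataframe(pd.DataFrame(x, columns=labels))
        halves = []
        for part in (x[:30], x[30:]):
            m = part.mean(axis=0)
            d = part - m
            halves.append(PatternGroup(np.arange(3), 30, m, d.T @ d / 30))
        split = MomentData(
            means=whole.means, cov=whole.cov, n=60, labels=labels,
            pattern_groups=halves,
        )
        mu = np.array([0.1, 0.0, -0.1])
        sigma = np.diag([1.0, 2.0, 0.5])
        assert fiml_fit_value(split, mu, sigma) == pytest.approx(
            ml_fit_value(whole, mu, sigma)
        )

    def test_disjoint_variable_sets_sum_their_marginals(self):
        # two equal-size groups observing disjoint halves of an uncorrelated Sigma
        labels = list("abcd")
        g1 = PatternGroup(np.array([0, 1]), 10, np.zeros(2), np.eye(2))
        g2 = PatternGroup(np.array([2, 3]), 10, np.zeros(2), 2.0 * np.eye(2))
        data = MomentData(
            means=np.zeros(4), cov=np.eye(4), n=20, labels=labels,
            pattern_groups=[g1, g2],
        )
        sigma = np.diag([1.0, 1.0, 2.0, 2.0])
        f1 = 2.0  # trace 2, quad 0, logdet 0
        f2 = 2.0 + np.log(4.0) - np.log(4.0)  # trace(2I * inv(2I)) = 2
        expected = 0.5 * (f1 + (2.0 + 2 * np.log(2.0)))
        assert fiml_fit_value(data, np.zeros(4), sigma) == pytest.approx(expected)

    def test_singleton_pattern_has_no_scatter_term(self):
        labels = ["a", "b"]
        z = np.array([1.0, 2.0])
        g = PatternGroup(np.array([0, 1]), 1, z, np.zeros((2, 2)))
        data = MomentData(
            means=z, cov=np.zeros((2, 2)), n=1, labels=labels, pattern_groups=[g]
        )
        sigma = np.diag([2.0, 2.0])
        expected = z @ np.linalg.inv(sigma) @ z + np.linalg.slogdet(sigma)[1]
        assert fiml_fit_value(data, np.zeros(2), sigma) == pytest.approx(expected)

    def test_all_missing_rows_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, np.nan]})
        with pytest.raises(DataError):
            MomentData.from_dataframe(frame)


class TestFit:
    def test_parameter_recovery_large_n(self, rng):
        omega = np.zeros((4, 4))
        omega[0, 1] = omega[1, 0] = 0.3
        omega[2, 3] = omega[3, 2] = -0.25
        truth = GaussianNetwork(omega=omega, delta=np.array([1.0, 1.2, 0.9, 1.1]))
        sigma = network_to_covariance(truth)
        mu = np.array([1.0, 2.0, 0.0, -1.0])
        n = 100_000
        data = MomentData.from_dataframe(
            _mvn_frame(rng, mu, sigma, n, list("abcd"))
        )
        res = fit(CrossSectionalSpec(labels=list("abcd")), data, method="ml")
        assert res.converged
        est = res.model.matrices()
        # within 3 Monte-Carlo standard errors (partial correlations: ~1/sqrt(n))
        tol = 3.0 / np.sqrt(n)
        assert np.max(np.abs(est["omega"] - omega)) < 5 * tol
        assert np.max(np.abs(est["mu"] - mu)) < 5 * tol

    def test_saturated_fit_has_zero_chi_square_and_df(self, rng):
        data = MomentData.from_dataframe(
            _mvn_frame(rng, np.zeros(3), np.eye(3), 500, list("abc"))
        )
        res = fit(CrossSectionalSpec(labels=list("abc")), data, method="ml")
        assert res.df == 0
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)

    def test_refit_from_solution_is_idempotent(self, ts_blank, ts_data):
        first = fit(ts_blank, ts_data, method="ml")
        again = fit(
            first.model, ts_data, method="ml",
            warm_start=first.model.free_vector(), start_from_data=False,
        )
        assert again.fvalue == pytest.approx(first.fvalue, abs=1e-8)
        assert np.allclose(
            again.model.free_vector(), first.model.free_vector(), atol=1e-4
        )

    def test_label_mismatch_rejected(self, ts_blank):
        bad = MomentData.from_moments(np.zeros(2), np.eye(2), 10, ["x", "y"])
        with pytest.raises(DataError):
            fit(ts_blank, bad)

    def test_ml_requires_complete_data(self, ts_blank, ts_dataset):
        from lvgvar.io import timeseries_moments

        incomplete = timeseries_moments(ts_dataset, method="fiml")
        with pytest.raises(DataError):
            fit(ts_blank, incomplete, method="ml")


class TestStandardErrors:
    def test_mean_se_is_sigma_over_sqrt_n(self, rng):
        n = 4000
        data = MomentData.from_dataframe(
            _mvn_frame(rng, [0.0], [[4.0]], n, ["a"])
        )
        res = fit(CrossSectionalSpec(labels=["a"]), data, method="ml")
        se = standard_errors(res)
        sd_hat = res.model.matrices()["delta"][0]
        assert se["mu[a]"] == pytest.approx(sd_hat / np.sqrt(n), rel=1e-3)

    def test_monte_carlo_calibration(self, rng):
        # empirical SD of estimates over replicates matches the mean reported SE
        omega = np.zeros((3, 3))
        omega[0, 1] = omega[1, 0] = 0.3
        truth = GaussianNetwork(omega=omega)
        sigma = network_to_covariance(truth)
        ests, ses = [], []
        for rep in range(120):
            sub = np.random.default_rng(1000 + rep)
            data = MomentData.from_dataframe(
                _mvn_frame(sub, np.zeros(3), sigma, 2000, list("abc"))
            )
            res = fit(CrossSectionalSpec(labels=list("abc")), data, method="ml")
            se = standard_errors(res)
            ests.append(res.estimates["omega[b,a]"])
            ses.append(se["omega[b,a]"])
        ratio = np.std(ests) / np.mean(ses)
        assert 0.8 < ratio < 1.2

    def test_fixed_parameters_have_no_se_entries(self, ts_blank, ts_data):
        res = fit(ts_blank, ts_data, method="ml")
        se = standard_errors(res)
        fixed = [p.name for p in res.model.params if not p.free]
        assert fixed and not (set(fixed) & set(se))


class TestChiSquareAndIndices:
    def test_rmsea_clamped_at_zero_when_chi2_below_df(self):
        res = _dummy_result(chi2=100.0, df=150, n=500)
        assert res.rmsea == 0.0

    def test_rmsea_ci_brackets_point_estimate(self, rng, panel_blank, panel_data):
        res = fit(panel_blank, panel_data, method="ml")
        assert res.rmsea_ci[0] <= res.rmsea + 1e-9
        assert res.rmsea_ci[1] >= res.rmsea - 1e-9

    def test_incremental_indices_present_and_bounded(self, panel_blank, panel_data):
        res = fit(panel_blank, panel_data, method="ml")
        assert res.df > 0
        for name in ("NFI", "PNFI", "TLI", "RFI", "IFI", "RNI", "CFI"):
            assert name in res.indices
        assert 0.0 <= res.indices["CFI"] <= 1.0
        assert 0.0 <= res.indices["TLI"] <= 1.0


def _dummy_result(chi2, df, n):
    """RMSEA arithmetic on externally supplied chi-square / df / n."""
    from lvgvar.estimation import FitResult

    labels = ["x"]
    data = MomentData.from_moments(np.zeros(1), np.eye(1), n, labels)
    spec = CrossSectionalSpec(labels=labels)
    model = compile_spec(spec)
    f_sat = saturated_fit_value(data)
    res = FitResult(
        model=model, data=data, method="ml",
        fvalue=f_sat + chi2 / n, loglik=0.0,
        n_free=0, df=df, converged=True,
    )
    res.df = df
    return chi_square_and_indices(res)


class TestCompare:
    def test_identical_fits_give_zero_differences(self, panel_blank, panel_data):
        res = fit(panel_blank, panel_data, method="ml")
        out = compare(res, res)
        assert out["delta_chi_square"] == pytest.approx(0.0)
        assert out["delta_df"] == 0
        assert out["p_value"] == 1.0

    def test_delta_chi_square_equals_n_delta_f(self, panel_blank, panel_data):
        full = fit(panel_blank, panel_data, method="ml")
        model = full.model
        edge = next(p.name for p in model.params if p.family == "temporal" and p.free)
        nested = fit(
            model.with_fixed(edge), panel_data, method="ml",
            warm_start=None, start_from_data=False,
        )
        out = compare(nested, full)
        assert out["delta_chi_square"] == pytest.approx(
            panel_data.n * (nested.fvalue - full.fvalue)
        )
        assert out["delta_df"] == 1
        # algebraic identity on the same data: dAIC = dChi2 - 2 dk
        assert out["delta_aic"] == pytest.approx(
            out["delta_chi_square"] - 2 * out["delta_df"], abs=1e-6
        )

    def test_non_nested_comparison_rejected(self, panel_blank, panel_data):
        full = fit(panel_blank, panel_data, method="ml")
        edge = next(p.name for p in full.model.params if p.family == "temporal")
        nested = fit(
            full.model.with_fixed(edge), panel_data, method="ml",
            start_from_data=False,
        )
        with pytest.raises(ValueError):
            compare(full, nested)


class TestFimlSaturated:
    def test_em_saturated_matches_complete_closed_form(self, rng):
        x = rng.normal(size=(80, 3))
        frame = pd.DataFrame(x, columns=list("abc"))
        complete = MomentData.from_dataframe(frame)
        # knock out a few cells to create a second pattern
        frame2 = frame.copy()
        frame2.iloc[:10, 0] = np.nan
        incomplete = MomentData.from_dataframe(frame2)
        f_complete = saturated_fit_value(complete, "fiml")
        f_incomplete = saturated_fit_value(incomplete, "fiml")
        assert f_complete == pytest.approx(3 + np.linalg.slogdet(complete.cov)[1])
        # with little missingness the saturated values stay close
        assert abs(f_incomplete - f_complete) < 0.5

    def test_fiml_chi_square_on_incomplete_ts_data(self, ts_blank, ts_dataset):
        from lvgvar.io import timeseries_moments

        data = timeseries_moments(ts_dataset, method="fiml")
        res = fit(ts_blank, data, method="fiml")
        assert res.converged
        assert res.chi_square >= 0.0
        assert res.df == 0  # observed-variable saturated ts layout
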