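"""Spline basis, Cox partial-likelihood fitting, PH diagnostics."""

import numpy as np
import pandas as pd
import pytest

import gabadose as g
from gabadose.cox import (
    RCSBasis,
    build_design_matrix,
    ph_diagnostics,
    rcs_basis,
    report_factors,
    spline_curve,
)
from gabadose.errors import ConvergenceError, DataError


class TestRCSBasis:
    def test_linear_function_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 400)
        y = 3.0 + 2.0 * x
        basis = rcs_basis(x, df=5)
        B = np.column_stack([np.ones_like(x), basis.transform(x)])
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        np.testing.assert_allclose(B @ coef, y, atol=1e-8)

    def test_linear_beyond_boundary_knots(self):
        """Natural-spline property: zero curvature outside the boundary
        knots (second differences vanish there)."""
        x = np.random.default_rng(1).uniform(0, 1, 300)
        basis = rcs_basis(x, df=4)
        grid = np.linspace(basis.knots[-1] + 0.1, basis.knots[-1] + 2, 50)
        B = basis.transform(grid)
        second = np.diff(B, n=2, axis=0)
        np.testing.assert_allclose(second, 0, atol=1e-8)
        grid_lo = np.linspace(basis.knots[0] - 2, basis.knots[0] - 0.1, 50)
        np.testing.assert_allclose(np.diff(basis.transform(grid_lo), n=2, axis=0), 0, atol=1e-8)

    def test_df5_knots_at_standard_quantiles(self):
        x = np.linspace(0, 1, 10001)
        basis = rcs_basis(x, df=5)
        np.testing.assert_allclose(
            basis.knots, [0.05, 0.23, 0.41, 0.59, 0.77, 0.95], atol=1e-3
        )
        assert basis.transform(x).shape == (len(x), 5)

    def test_insufficient_distinct_values_suggests_lower_df(self):
        with pytest.raises(DataError, match="lower df"):
            rcs_basis(np.array([1, 2, 3, 1, 2, 3], dtype=float), df=5)


def efron_partial_loglik(beta, x, time, event):
    """Direct enumeration of the Efron partial likelihood (equals the
    Breslow form when event times are unique)."""
    beta = np.atleast_1d(beta)
    x = np.atleast_2d(x.T).T
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        risk = time >= t
        d = tied.sum()
        theta = np.exp(x @ beta)
        sum_risk = theta[risk].sum()
        sum_tied = theta[tied].sum()
        ll += float((x[tied] @ beta).sum())
        for l in range(d):
            ll -= np.log(sum_risk - l / d * sum_tied)
    return ll


def toy_records(times, events, z):
    return pd.DataFrame(
        {"time_days": times, "event": events, "z": z}
    )


BINARY_SPEC = g.ModelSpec(
    binary_covariates=("z",), categorical_covariates={}, spline_covariates={}
)


class TestFitCox:
    def test_tiny_data_matches_grid_search_oracle(self):
        rec = toy_records([2.0, 5.0, 7.0, 11.0], [1, 1, 0, 1], [1.0, 0.0, 1.0, 0.0])
        fit = g.fit_cox(rec, BINARY_SPEC)
        grid = np.linspace(-4, 4, 20001)
        x = rec["z"].to_numpy()
        lls = [
            efron_partial_loglik(b, x, rec["time_days"].to_numpy(), rec["event"].to_numpy())
            for b in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert fit.coefficients["z"] == pytest.approx(best, abs=1e-3)

    def test_loglik_matches_direct_enumeration(self):
        rng = np.random.default_rng(4)
        times = rng.permutation(np.arange(1.0, 9.0))  # 8 obs, no ties
        events = np.array([1, 0, 1, 1, 0, 1, 1, 0])
        z = rng.normal(size=8)
        rec = toy_records(times, events, z)
        fit = g.fit_cox(rec, BINARY_SPEC)
        ll = efron_partial_loglik(
            fit.coefficients.to_numpy(), z, times, events
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-10)

    def test_constant_covariate_excluded_others_unchanged(self):
        rng = np.random.default_rng(5)
        n = 300
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(100 / np.exp(0.7 * z))
        rec = pd.DataFrame(
            {"time_days": t, "event": 1, "z": z, "null_flag": 0.0}
        )
        spec2 = g.ModelSpec(
            binary_covariates=("z", "null_flag"),
            categorical_covariates={}, spline_covariates={},
        )
        fit2 = g.fit_cox(rec, spec2)
        fit1 = g.fit_cox(rec, BINARY_SPEC)
        assert "null_flag" not in fit2.coefficients.index
        assert "null_flag" in fit2.design_info.dropped_terms
        assert fit2.coefficients["z"] == pytest.approx(fit1.coefficients["z"], rel=1e-10)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(6)
        n = 200
        z = rng.normal(size=n)
        t = rng.exponential(100 / np.exp(0.5 * z))
        rec = toy_records(t, np.ones(n, dtype=int), z)
        efron = g.fit_cox(rec, BINARY_SPEC)
        breslow = g.fit_cox(
            rec,
            g.ModelSpec(binary_covariates=("z",), categorical_covariates={},
                        spline_covariates={}, ties_method="breslow"),
        )
        assert breslow.coefficients["z"] == pytest.approx(
            efron.coefficients["z"], abs=1e-6
        )
        assert breslow.loglik == pytest.approx(efron.loglik, abs=1e-6)
        # covariances cross-check: model-based and robust each agree across
        # the two independent implementations
        np.testing.assert_allclose(
            breslow.covariance_model.to_numpy(),
            efron.covariance_model.to_numpy(), rtol=1e-4,
        )
        np.testing.assert_allclose(
            breslow.covariance_robust.to_numpy(),
            efron.covariance_robust.to_numpy(), rtol=1e-3,
        )

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(7)
        n = 4000
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1000 / np.exp(np.log(2.0) * z))
        cap = 730.0
        rec = toy_records(np.minimum(t, cap), (t <= cap).astype(int), z)
        fit = g.fit_cox(rec, BINARY_SPEC)
        hr = fit.hr_with_ci().iloc[0]
        assert hr["ci_low"] < 2.0 < hr["ci_high"]

    def test_separation_raises_convergence_error(self):
        # perfectly separated: all events in one group, huge follow-up gap
        rec = toy_records(
            [1.0, 2.0, 3.0, 100.0, 110.0, 120.0],
            [1, 1, 1, 0, 0, 0],
            [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        )
        spec = g.ModelSpec(binary_covariates=("z",), categorical_covariates={},
                           spline_covariates={}, ties_method="breslow")
        with pytest.raises(ConvergenceError):
            g.fit_cox(rec, spec)

    def test_too_few_events_rejected(self):
        rec = toy_records([1.0, 2.0, 3.0], [1, 0, 0], [1.0, 0.0, 1.0])
        with pytest.raises(DataError, match="2 events"):
            g.fit_cox(rec, BINARY_SPEC)

    def test_robust_and_model_variance_agree_under_correct_model(self):
        rng = np.random.default_rng(9)
        n = 20_000
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(500 / np.exp(0.5 * z))
        rec = toy_records(t, np.ones(n, dtype=int), z)
        fit = g.fit_cox(rec, BINARY_SPEC)
        ratio = (
            fit.covariance_robust.loc["z", "z"] / fit.covariance_model.loc["z", "z"]
        )
        assert ratio == pytest.approx(1.0, rel=0.05)


class TestDesignMatrix:
    def test_complete_case_drops_missing_rows(self):
        df = pd.DataFrame(
            {
                "time_days": [1.0, 2, 3, 4],
                "event": [1, 1, 0, 1],
                "z": [1.0, 0, np.nan, 1],
            }
        )
        X, info, dropped = build_design_matrix(df, BINARY_SPEC)
        assert dropped == 1 and len(X) == 3

    def test_categorical_reference_level_omitted(self):
        df = pd.DataFrame(
            {
                "spec": ["general_practitioner", "neurologist", "psychiatrist"] * 10,
            }
        )
        spec = g.ModelSpec(
            binary_covariates=(),
            categorical_covariates={"spec": "general_practitioner"},
            spline_covariates={},
        )
        X, info, _ = build_design_matrix(df, spec)
        assert set(X.columns) == {"spec[neurologist]", "spec[psychiatrist]"}

    def test_spline_df_degrades_on_few_distinct_values(self):
        df = pd.DataFrame({"n_prescribers": np.tile([1.0, 2, 3, 4], 50)})
        spec = g.ModelSpec(
            binary_covariates=(), categorical_covariates={},
            spline_covariates={"n_prescribers": 5},
        )
        with pytest.warns(UserWarning):
            X, info, _ = build_design_matrix(df, spec)
        assert "n_prescribers_rcs1" in X.columns


class TestReportFactors:
    def _degenerate_fit(self):
        idx = pd.Index(["z"])
        zero = pd.DataFrame(np.zeros((1, 1)), index=idx, columns=idx)
        from gabadose.cox import CoxFit, DesignInfo

        return CoxFit(
            coefficients=pd.Series([np.log(2.0)], index=idx),
            covariance_robust=zero,
            covariance_model=zero,
            loglik=0.0,
            n_used=10,
            n_events=5,
            n_dropped_missing=0,
            ties_method="efron",
            variance="robust",
            design_info=DesignInfo([], {}, {}, []),
        )

    def test_degenerate_se_gives_point_ci(self):
        table = self._degenerate_fit().hr_with_ci()
        row = table.iloc[0]
        assert row["hr"] == pytest.approx(2.0)
        assert row["ci_low"] == pytest.approx(2.0)
        assert row["ci_high"] == pytest.approx(2.0)

    def test_spline_curve_is_one_at_reference(self):
        rng = np.random.default_rng(10)
        n = 2000
        age = rng.uniform(20, 90, n)
        t = rng.exponential(400.0, n)
        rec = pd.DataFrame({"time_days": t, "event": 1, "age": age})
        spec = g.ModelSpec(binary_covariates=(), categorical_covariates={},
                           spline_covariates={"age": 5})
        fit = g.fit_cox(rec, spec)
        ref = fit.design_info.spline_refs["age"]
        curve = spline_curve(fit, "age", grid=[ref])
        assert curve["hr"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_forest_row_count_matches_terms(self):
        rng = np.random.default_rng(11)
        n = 500
        rec = pd.DataFrame(
            {
                "time_days": rng.exponential(100, n),
                "event": 1,
                "a": rng.integers(0, 2, n).astype(float),
                "b": rng.integers(0, 2, n).astype(float),
            }
        )
        spec = g.ModelSpec(binary_covariates=("a", "b"),
                           categorical_covariates={}, spline_covariates={})
        fit = g.fit_cox(rec, spec)
        out = report_factors(fit)
        assert len(out["forest"]) == 2


class TestPHDiagnostics:
    def _ph_data(self, n=2000, beta=0.5, seed=12):
        rng = np.random.default_rng(seed)
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(500 / np.exp(beta * z))
        cap = 730.0
        return toy_records(np.minimum(t, cap), (t <= cap).astype(int), z)

    def test_beta_t_flat_under_proportional_hazards(self):
        rec = self._ph_data(n=5000)
        fit = g.fit_cox(rec, BINARY_SPEC)
        diag = ph_diagnostics(fit)
        curve = diag.beta_t["z"]
        b = fit.coefficients["z"]
        # the smoothed time-varying coefficient stays near the fitted value
        assert np.abs(curve["beta"] - b).mean() < 0.25

    def test_nonproportional_covariate_detected(self):
        """A hazard ratio reversing mid-follow-up is flagged by the test."""
        rng = np.random.default_rng(13)
        n = 10_000
        z = rng.integers(0, 2, n).astype(float)
        # piecewise exponential: HR 2 before t=200, HR 0.5 after
        h0 = 1 / 500.0
        t = np.empty(n)
        for i in range(n):
            h1 = h0 * (2.0 if z[i] else 1.0)
            t1 = rng.exponential(1 / h1)
            if t1 <= 200:
                t[i] = t1
            else:
                h2 = h0 * (0.5 if z[i] else 1.0)
                t[i] = 200 + rng.exponential(1 / h2)
        cap = 730.0
        rec = toy_records(np.minimum(t, cap), (t <= cap).astype(int), z)
        fit = g.fit_cox(rec, BINARY_SPEC)
        diag = ph_diagnostics(fit)
        assert diag.per_covariate.loc[0, "p"] < 0.05
        assert diag.global_p < 0.05

    def test_time_transforms_supported(self):
        rec = self._ph_data()
        fit = g.fit_cox(rec, BINARY_SPEC)
        for transform in ("km", "rank", "identity"):
            diag = ph_diagnostics(fit, time_transform=transform)
            assert diag.global_chi_square >= 0
            assert 0 <= diag.global_p <= 1

    def test_too_few_events_rejected(self):
        rec = toy_records(
            np.arange(1.0, 13.0), [1] * 5 + [0] * 7, np.tile([0.0, 1], 6)
        )
        fit = g.fit_cox(rec, BINARY_SPEC)
        with pytest.raises(DataError):
            ph_diagnostics(fit)
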