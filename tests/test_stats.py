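"""Correlation screen, VIF filter and stepwise regression."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xcprofile import reference
from xcprofile.errors import MissingPredictor, SampleTooSmall
from xcprofile.stats import (
    RegressionReport,
    _exact_spearman_p,
    _ols,
    _sum_d2_null_counts,
    analyze_markers,
    backward_eliminate,
    compute_vifs,
    correlation_screen,
    f_from_r2,
    forward_select_and_fit,
    predict_race_time,
    shapiro_wilk_screen,
    spearman_rho,
    spearman_with_ci,
    vif_filter,
)


class TestShapiroScreen:
    def test_constant_column_flagged(self):
        frame = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        out = shapiro_wilk_screen(frame).set_index("variable")
        assert out.loc["a", "flag"] == "constant_column"
        assert np.isfinite(out.loc["b", "p_value"])

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            x = rng.standard_t(1, size=50)
            p = shapiro_wilk_screen(pd.DataFrame({"x": x}))["p_value"][0]
            hits += p < 0.05
        assert hits > 36  # > 90% power against t_1

    def test_normal_type_one_rate(self):
        rng = np.random.default_rng(1)
        hits = sum(
            shapiro_wilk_screen(
                pd.DataFrame({"x": rng.standard_normal(40)}))["p_value"][0]
            < 0.05
            for _ in range(300))
        assert 0.01 < hits / 300 < 0.10


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([1.0, 2.5, 3.0, 4.7, 8.0, 9.1])
        y = np.exp(x)
        assert spearman_rho(x, y) == pytest.approx(1.0)
        assert spearman_rho(x, -np.sqrt(y)) == pytest.approx(-1.0)
        # strictly monotone transform of x leaves rho unchanged
        z = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman_rho(x ** 3, z) == pytest.approx(spearman_rho(x, z))

    def test_closed_form_rank_formula(self, rng):
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        d = sps.rankdata(x) - sps.rankdata(y)
        oracle = 1.0 - 6.0 * np.sum(d ** 2) / (10 * 99)
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_exact_null_matches_enumeration(self):
        n = 5
        counts = np.zeros(n * (n * n - 1) // 3 + 1)
        for perm in itertools.permutations(range(n)):
            counts[sum((i - p) ** 2 for i, p in enumerate(perm))] += 1
        assert np.allclose(_sum_d2_null_counts(n), counts)

    def test_exact_p_perfect_correlation(self):
        # only the identity and reversal reach |rho| = 1
        assert _exact_spearman_p(1.0, 6) == pytest.approx(2 / 720)

    def test_ci_shapes(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(10)
        y = 0.8 * x + 0.3 * rng.standard_normal(10)
        res = spearman_with_ci(x, y, n_boot=2000, seed=0, variable="v")
        lo, hi = res.ci95
        assert -1.0 <= lo <= res.rho <= hi <= 1.0
        assert res.p_method == "exact_permutation"
        fz = spearman_with_ci(x, y, ci_method="fisher-z")
        assert -1.0 <= fz.ci95[0] <= fz.ci95[1] <= 1.0

    def test_bootstrap_ci_clamps_at_one(self):
        # strongly monotone small sample: upper percentile hits 1.0
        x = np.arange(10.0)
        y = x + 0.01 * np.random.default_rng(0).standard_normal(10)
        res = spearman_with_ci(x, y, n_boot=2000, seed=1)
        assert res.ci95[1] == 1.0


class TestCorrelationScreen:
    def test_monotone_candidate_retained(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10)
        frame = pd.DataFrame({"x": x, "noise": rng.standard_normal(10),
                              "race_time_min": np.exp(x)})
        results = correlation_screen(frame, "race_time_min", n_boot=0)
        by_var = {r.variable: r for r in results}
        assert by_var["x"].retained
        assert by_var["x"].rho == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        frame = pd.DataFrame({"x": [1.0] * 8,
                              "race_time_min": np.arange(8.0)})
        res = correlation_screen(frame, "race_time_min", n_boot=0)[0]
        assert res.flag == "zero_rank_variance"
        assert not res.retained


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        n = 8
        base = np.eye(n)[:, :3] - 1.0 / n
        frame = pd.DataFrame(base, columns=["a", "b", "c"])
        vifs = compute_vifs(frame, ["a", "b", "c"])
        for value in vifs.values():
            assert value == pytest.approx(1.0, abs=0.35)
        retained, _ = vif_filter(frame, ["a", "b", "c"])
        assert retained == ["a", "b", "c"]

    def test_near_duplicate_removed(self):
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal(30)
        frame = pd.DataFrame({"x1": x1,
                              "x2": x1 + rng.normal(0, 1e-6, 30),
                              "x3": rng.standard_normal(30)})
        retained, table = vif_filter(frame, ["x1", "x2", "x3"])
        assert len(retained) == 2
        assert "x3" in retained
        assert any(step["removed"] in ("x1", "x2") for step in table)

    def test_perfect_collinearity_flagged(self):
        x1 = np.arange(12.0)
        frame = pd.DataFrame({"x1": x1, "x2": 2.0 * x1 + 1.0,
                              "x3": np.random.default_rng(0)
                              .standard_normal(12)})
        retained, table = vif_filter(frame, ["x1", "x2", "x3"])
        assert len(retained) == 2
        assert any(step["flag"] == "InfiniteVIF" for step in table)

    def test_statsmodels_oracle_identity(self, rng):
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )

        for _ in range(20):
            X = rng.standard_normal((25, 4))
            X[:, 1] = 0.7 * X[:, 0] + 0.3 * X[:, 1]
            frame = pd.DataFrame(X, columns=list("abcd"))
            mine = compute_vifs(frame, list("abcd"))
            design = np.column_stack([np.ones(25), X])
            for j, name in enumerate("abcd"):
                oracle = variance_inflation_factor(design, j + 1)
                assert mine[name] == pytest.approx(oracle, rel=1e-8)


class TestBackwardElimination:
    def test_noise_predictor_eliminated(self):
        rng = np.random.default_rng(5)
        x1 = rng.standard_normal(50)
        frame = pd.DataFrame({"x1": x1, "x2": rng.standard_normal(50),
                              "y": 3.0 * x1 + rng.normal(0, 0.5, 50)})
        kept, trace = backward_eliminate(frame, "y", ["x1", "x2"])
        assert kept == ["x1"]
        assert trace[0]["removed"] == "x2"

    def test_significant_single_predictor_kept(self):
        x = np.arange(20.0)
        frame = pd.DataFrame({"x": x, "y": 2.0 * x + 0.1})
        kept, trace = backward_eliminate(frame, "y", ["x"])
        assert kept == ["x"]
        assert trace == []

    def test_trace_bounded_by_predictor_count(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.standard_normal((15, 5)),
                             columns=list("abcde"))
        frame["y"] = rng.standard_normal(15)
        kept, trace = backward_eliminate(frame, "y", list("abcde"))
        assert len(trace) <= 5 + 1


class TestForwardSelection:
    def test_exact_recovery_of_reference_equation(self):
        # noiseless outcome built from the published equation
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({
            "po_x2": rng.normal(3.24, 0.49, 30),
            "po_x4": rng.normal(3.86, 0.43, 30),
            "po_vo2max": rng.normal(5.29, 0.38, 30),
        })
        frame["race_time_min"] = [
            reference.predicted_race_time_min(v, x4, x2)
            for v, x4, x2 in zip(frame["po_vo2max"], frame["po_x4"],
                                 frame["po_x2"])]
        report = forward_select_and_fit(
            frame, "race_time_min", ["po_x2", "po_x4", "po_vo2max"])
        assert report.intercept == pytest.approx(255.86, abs=1e-6)
        assert report.coefficients["po_vo2max"] == pytest.approx(-32.87,
                                                                 abs=1e-6)
        assert report.coefficients["po_x4"] == pytest.approx(-51.18,
                                                             abs=1e-6)
        assert report.coefficients["po_x2"] == pytest.approx(60.77, abs=1e-6)
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_df_bookkeeping_n9(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.standard_normal((9, 3)),
                             columns=["a", "b", "c"])
        frame["race_time_min"] = (80 - 5 * frame["a"] + 4 * frame["b"]
                                  - 3 * frame["c"])
        report = forward_select_and_fit(frame, "race_time_min",
                                        ["a", "b", "c"])
        assert report.df == (3, 5)

    def test_constant_outcome_intercept_only(self):
        frame = pd.DataFrame({"a": np.arange(10.0),
                              "race_time_min": [80.0] * 10})
        report = forward_select_and_fit(frame, "race_time_min", ["a"])
        assert report.coefficients == {}
        assert report.intercept == pytest.approx(80.0)
        assert report.r_squared == 0.0

    def test_f_r2_consistency_and_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(25):
            n = int(rng.integers(10, 40))
            X = rng.standard_normal((n, 2))
            y = X @ rng.normal(0, 2, 2) + rng.standard_normal(n)
            frame = pd.DataFrame(X, columns=["a", "b"])
            frame["y"] = y
            fit = _ols(y, X)
            f_mine = f_from_r2(fit.r_squared, 2, n - 3)
            oracle = sm.OLS(y, sm.add_constant(X)).fit()
            assert fit.r_squared == pytest.approx(oracle.rsquared, rel=1e-10)
            assert f_mine == pytest.approx(oracle.fvalue, rel=1e-8)
            assert np.allclose(fit.p_values, oracle.pvalues, atol=1e-10)
            # reported F always equals the R^2 identity
            assert f_mine == pytest.approx(
                (fit.r_squared / 2) / ((1 - fit.r_squared) / (n - 3)),
                abs=1e-10)


class TestPrediction:
    def _reference_report(self):
        return RegressionReport(
            intercept=reference.RACE_TIME_INTERCEPT_MIN,
            coefficients=dict(reference.RACE_TIME_COEFFICIENTS),
            r_squared=0.82, f_stat=7.52, df=(3, 5), p_value=0.03, n=9)

    def test_reference_inputs(self):
        report = self._reference_report()
        out = predict_race_time(report, {"po_vo2max": 5.29, "po_x4": 3.86,
                                         "po_x2": 3.24})
        assert out == pytest.approx(81.3177, abs=1e-10)

    def test_zero_slopes_return_intercept(self):
        report = RegressionReport(intercept=77.0, coefficients={},
                                  r_squared=0.0, f_stat=0.0, df=(0, 8),
                                  p_value=1.0, n=9)
        assert predict_race_time(report, {}) == 77.0

    def test_affine_linearity(self):
        report = self._reference_report()
        base = {"po_vo2max": 5.0, "po_x4": 4.0, "po_x2": 3.0}
        shifted = {k: v + 0.5 for k, v in base.items()}
        delta = sum(reference.RACE_TIME_COEFFICIENTS.values()) * 0.5
        assert predict_race_time(report, shifted) - predict_race_time(
            report, base) == pytest.approx(delta, abs=1e-10)

    def test_missing_predictor(self):
        with pytest.raises(MissingPredictor):
            predict_race_time(self._reference_report(), {"po_x2": 3.2})


class TestAnalyzeMarkers:
    def test_sample_too_small(self):
        frame = pd.DataFrame({"a": np.arange(5.0),
                              "race_time_min": np.arange(5.0)})
        with pytest.raises(SampleTooSmall):
            analyze_markers(frame, "race_time_min")

    def test_unbiased_coefficients_with_noise(self):
        # moderate race noise, analysis stage on the true predictors
        rng = np.random.default_rng(10)
        sums = np.zeros(3)
        used = 0
        for _ in range(120):
            frame = pd.DataFrame({
                "po_x2": rng.normal(3.24, 0.49, 40),
                "po_x4": rng.normal(3.86, 0.43, 40),
                "po_vo2max": rng.normal(5.29, 0.38, 40),
            })
            frame["race_time_min"] = [
                reference.predicted_race_time_min(v, x4, x2)
                for v, x4, x2 in zip(frame["po_vo2max"], frame["po_x4"],
                                     frame["po_x2"])]
            frame["race_time_min"] += rng.normal(0, 1.0, 40)
            rep = forward_select_and_fit(frame, "race_time_min",
                                         ["po_x2", "po_x4", "po_vo2max"])
            if set(rep.coefficients) != {"po_x2", "po_x4", "po_vo2max"}:
                continue
            sums += [rep.coefficients["po_vo2max"],
                     rep.coefficients["po_x4"], rep.coefficients["po_x2"]]
            used += 1
        assert used > 100
        means = sums / used
        targets = np.array([-32.87, -51.18, 60.77])
        assert np.all(np.abs(means - targets) < 0.05 * np.abs(targets))
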