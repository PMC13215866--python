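from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from vepkit.quantiles import (
    check_loss,
    classify_pattern,
    compute_vif,
    cross_quantile_tests,
    design,
    fit_interactions,
    fit_ols,
    fit_quantile,
    full_quantile_sweep,
    subgroup_equality,
)


def brute_force_quantile_objective(X, y, tau):
    """Oracle: minimum check loss over all exact-fit coefficient vectors
    through p observations (an optimal basic solution passes through p points)."""
    n, p = X.shape
    best = np.inf
    for rows in combinations(range(n), p):
        A = X[list(rows)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        b = np.linalg.solve(A, y[list(rows)])
        best = min(best, check_loss(y - X @ b, tau))
    return best


class TestVif:
    def test_orthogonal_columns(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)])
        rep = compute_vif(X)
        assert np.allclose(rep.vif, 1.0, atol=1e-10)
        assert not rep.collinear

    def test_known_correlation_closed_form(self, rng):
        # build two columns with exact sample correlation 0.6
        n = 1000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        x2 = 0.6 * a + np.sqrt(1 - 0.36) * b
        rep = compute_vif(np.column_stack([a, x2]))
        assert np.allclose(rep.vif, 1 / (1 - 0.36), atol=1e-9)

    def test_duplicated_column_infinite(self, rng):
        x = rng.standard_normal(100)
        rep = compute_vif(np.column_stack([x, x]))
        assert np.all(np.isinf(rep.vif))
        assert rep.collinear

    def test_vif_at_least_one(self, rng):
        X = rng.standard_normal((200, 5))
        rep = compute_vif(X)
        assert np.all(rep.vif >= 1.0 - 1e-12)

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        with pytest.raises(ValueError, match="constant"):
            compute_vif(X)


class TestFitQuantile:
    def test_intercept_only_median(self):
        y = np.array([1.0, 2, 3, 4, 100])
        X = np.ones((5, 1))
        fit = fit_quantile(X, y, 0.5, bootstrap_reps=0)
        assert fit.params[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("tau", [0.1, 0.25, 0.5, 0.75, 0.9])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_matches_brute_force(self, tau, seed):
        rng = np.random.default_rng(seed)
        n, p = 10, 2
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        fit = fit_quantile(X, y, tau, bootstrap_reps=0)
        oracle = brute_force_quantile_objective(X, y, tau)
        assert fit.objective == pytest.approx(oracle, abs=1e-8)

    def test_optimality_box(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1, 2] + rng.standard_normal(n)
        for tau in (0.25, 0.5, 0.75):
            fit = fit_quantile(X, y, tau, bootstrap_reps=0)
            neg = np.mean(fit.residuals < -1e-10)
            nonpos = np.mean(fit.residuals <= 1e-10)
            assert neg <= tau + 1e-9 <= nonpos + 1e-9
            assert nonpos >= tau - 1e-9

    def test_median_consistency_with_symmetric_noise(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        b = np.array([0.5, -1.2])
        y = X @ b + rng.laplace(size=n)
        fit = fit_quantile(X, y, 0.5, bootstrap_reps=100, seed=5)
        assert np.all(np.abs(fit.params - b) < 3 * fit.bse)

    def test_equivariance_scale_and_shift(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1, 0.3] + rng.standard_normal(n)
        base = fit_quantile(X, y, 0.3, bootstrap_reps=0).params
        scaled = fit_quantile(X, 5.0 * y, 0.3, bootstrap_reps=0).params
        shifted = fit_quantile(X, y + 7.0, 0.3, bootstrap_reps=0).params
        assert np.allclose(scaled, 5.0 * base, atol=1e-7)
        assert np.allclose(shifted[1:], base[1:], atol=1e-7)
        assert shifted[0] == pytest.approx(base[0] + 7.0, abs=1e-7)

    def test_invalid_tau(self, rng):
        X = np.ones((10, 1))
        with pytest.raises(ValueError):
            fit_quantile(X, np.arange(10.0), 1.5)

    def test_rank_deficient(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_quantile(X, x, 0.5, bootstrap_reps=0)


class TestFitOls:
    def test_exact_recovery(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        b = np.array([1.0, -2.0, 0.5])
        fit = fit_ols(X, X @ b)
        assert np.allclose(fit.params, b, atol=1e-10)

    def test_intercept_only_mean(self, rng):
        y = rng.standard_normal(100)
        fit = fit_ols(np.ones((100, 1)), y)
        assert fit.params[0] == pytest.approx(y.mean())

    def test_agrees_with_median_fit_under_symmetric_noise(self, rng):
        n = 3000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1, 0.8] + rng.standard_normal(n)
        ols = fit_ols(X, y)
        med = fit_quantile(X, y, 0.5, bootstrap_reps=100, seed=3)
        assert np.all(np.abs(ols.params - med.params) < 3 * med.bse)


class TestClassifyPattern:
    def test_published_v_shape(self):
        assert classify_pattern(-0.0411, -0.1353, -0.0820, True, True) == "V-shaped"

    def test_published_inverted_v(self):
        assert (
            classify_pattern(0.0367, 0.0838, 0.0354, True, True)
            == "Inverted V-shaped"
        )

    def test_monotone(self):
        assert classify_pattern(1.0, 2.0, 3.0, True, True) == "monotone"

    def test_strict_requires_significance(self):
        assert classify_pattern(0.0367, 0.0838, 0.0354, False, True) == "flat/other"

    def test_lenient_ignores_significance(self):
        # mirrors the migrant-workers row: first step non-significant
        assert (
            classify_pattern(0.0558, 0.0831, 0.0434, False, True, rule="lenient")
            == "Inverted V-shaped"
        )

    def test_tie_breaks_to_flat(self):
        assert classify_pattern(1.0, 1.0, 0.5, True, True) == "flat/other"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(np.nan, 0.0, 1.0, True, True)


class TestCrossQuantile:
    def test_heteroscedastic_power_exceeds_size(self, rng):
        # slope increases with tau when noise scale depends on x
        n = 2000
        x = rng.uniform(0, 2, n)
        X = np.column_stack([np.ones(n), x])
        y = 1 + 0.5 * x + (0.3 + 0.8 * x) * rng.standard_normal(n)
        tests = cross_quantile_tests(X, y, bootstrap_reps=100, seed=9,
                                     names=["const", "x"])
        assert tests[0].joint_pvalue < 0.05
        # slope ordering across taus is increasing
        assert tests[0].coefficients[0] < tests[0].coefficients[2]

    def test_degenerate_resampler_gives_zero_statistic(self, monkeypatch, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1, 0.5] + rng.standard_normal(n)

        class ConstantRng:
            def integers(self, lo, hi, size):
                return np.arange(size)

        monkeypatch.setattr(np.random, "default_rng", lambda seed=None: ConstantRng())
        with pytest.warns(RuntimeWarning, match="singular|pseudo"):
            tests = cross_quantile_tests(X, y, bootstrap_reps=8, names=["const", "x"])
        # identical draws -> zero bootstrap covariance -> statistic 0 via pinv
        assert tests[0].joint_stat == 0.0

    def test_variable_names_and_const_skipped(self, rng):
        n = 300
        tab = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        X, names = design(tab, ["a", "b"])
        y = X @ [0.5, 1.0, -1.0] + rng.standard_normal(n)
        tests = cross_quantile_tests(X, y, bootstrap_reps=30, seed=2, names=names)
        assert [t.variable for t in tests] == ["a", "b"]


class TestSubgroup:
    def test_identical_groups_zero_difference(self, rng):
        n = 200
        base = pd.DataFrame(
            {"x": rng.standard_normal(n), "y": rng.standard_normal(n)}
        )
        a = base.assign(g=0)
        b = base.assign(g=1)
        tab = pd.concat([a, b], ignore_index=True)
        out = subgroup_equality(tab, "g", "y", ["x"])
        assert np.allclose(out.equality_stat, 0.0, atol=1e-16)

    def test_group_specific_slope_detected(self, rng):
        n = 3000
        x = rng.standard_normal(2 * n)
        g = np.repeat([0, 1], n)
        slope = np.where(g == 1, 0.066, 0.0)
        y = 0.2 + slope * x + 0.3 * rng.standard_normal(2 * n)
        tab = pd.DataFrame({"x": x, "g": g, "y": y})
        out = subgroup_equality(tab, "g", "y", ["x"])
        j = out.names.index("x")
        assert out.equality_pvalue[j] < 0.05

    def test_nonbinary_group_rejected(self, rng):
        tab = pd.DataFrame({"x": rng.standard_normal(90), "g": np.tile([0, 1, 2], 30),
                            "y": rng.standard_normal(90)})
        with pytest.raises(ValueError, match="binary"):
            subgroup_equality(tab, "g", "y", ["x"])

    def test_small_group_rejected(self, rng):
        tab = pd.DataFrame({"x": rng.standard_normal(40),
                            "g": np.r_[np.zeros(35), np.ones(5)],
                            "y": rng.standard_normal(40)})
        with pytest.raises(ValueError, match="minimum"):
            subgroup_equality(tab, "g", "y", ["x"])


class TestInteractions:
    def test_null_interaction_near_zero(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        g = rng.integers(0, 2, n).astype(float)
        y = 1 + 0.5 * x - 0.3 * g + 0.4 * rng.standard_normal(n)
        tab = pd.DataFrame({"x": x, "g": g, "y": y})
        fit = fit_interactions(tab, "y", ["x", "g"], [("x", "g")])
        j = fit.names.index("x:g")
        assert abs(fit.params[j]) < 3 * fit.bse[j]

    def test_interaction_recovered(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        g = rng.integers(0, 2, n).astype(float)
        y = 1 + 0.5 * x - 0.3 * g + 0.05 * x * g + 0.2 * rng.standard_normal(n)
        tab = pd.DataFrame({"x": x, "g": g, "y": y})
        fit = fit_interactions(tab, "y", ["x", "g"], [("x", "g")])
        j = fit.names.index("x:g")
        assert abs(fit.params[j] - 0.05) < 3 * fit.bse[j]

    def test_disjoint_indicator_product_rejected(self):
        tab = pd.DataFrame(
            {"a": [1.0, 1, 0, 0], "b": [0.0, 0, 1, 1], "y": [1.0, 2, 3, 4]}
        )
        with pytest.raises(np.linalg.LinAlgError, match="a:b"):
            fit_interactions(tab, "y", ["a", "b"], [("a", "b")])


class TestSweep:
    def test_single_value_grid_matches_fit(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1, 0.5] + rng.standard_normal(n)
        tidy = full_quantile_sweep(X, y, tau_grid=[0.5], bootstrap_reps=0,
                                   names=["const", "x"])
        direct = fit_quantile(X, y, 0.5, bootstrap_reps=0, names=["const", "x"])
        got = tidy.set_index("variable").loc["x", "coefficient"]
        assert got == pytest.approx(direct.params[1], abs=1e-10)

    def test_location_shift_curves_flat(self, rng):
        n = 3000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1, 0.7] + rng.standard_normal(n)
        tidy = full_quantile_sweep(X, y, tau_grid=[0.2, 0.4, 0.6, 0.8],
                                   bootstrap_reps=0, names=["const", "x"])
        slopes = tidy[tidy.variable == "x"].coefficient.to_numpy()
        assert np.ptp(slopes) < 0.15

    def test_mid_quantile_dip_for_v_design(self, rng):
        # DGP with conditional quantile Q(tau|x) = z_tau + x * (1 + 0.5|z_tau|):
        # monotone in tau for x in [0,1], slope curve minimal exactly at tau=0.5
        from scipy import stats as st

        n = 8000
        x = rng.uniform(0, 1, n)
        z = rng.standard_normal(n)
        y = z + x * (1 + 0.5 * np.abs(z))
        X = np.column_stack([np.ones(n), x])
        taus_grid = [0.2, 0.35, 0.5, 0.65, 0.8]
        tidy = full_quantile_sweep(X, y, tau_grid=taus_grid, bootstrap_reps=0,
                                   names=["const", "x"])
        slopes = tidy[tidy.variable == "x"].set_index("tau").coefficient
        assert slopes.idxmin() == 0.5
        # and the fitted slopes track the analytic curve 1 + 0.5|z_tau|
        truth = 1 + 0.5 * np.abs(st.norm.ppf(taus_grid))
        assert np.allclose(slopes.to_numpy(), truth, atol=0.15)
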