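import itertools

import numpy as np
import pytest

from enzopt import QuadraticResponseSurface, generate_bbd
from enzopt.datasets import REPORTED_COEFFICIENTS
from enzopt.rsm import _expand
from enzopt.simulate import TruthSurface, replicate_means_design, simulate_bbd_dataset


class TestFit:
    def test_recovers_exact_coefficients_on_noise_free_data(self, factors, rng):
        beta = rng.normal(size=10) * 10
        design = generate_bbd(factors, center_points=3)
        y = _expand(design.actual) @ beta
        model = QuadraticResponseSurface().fit(design.actual, y)
        np.testing.assert_allclose(
            np.concatenate([[model.intercept_], model.coef_]), beta, rtol=1e-8
        )

    def test_shift_equivariance(self, amylase_table):
        y = amylase_table.response("specific_activity")
        X = amylase_table.actual
        base = QuadraticResponseSurface().fit(X, y)
        shifted = QuadraticResponseSurface().fit(X, y + 500.0)
        assert shifted.intercept_ == pytest.approx(base.intercept_ + 500.0)
        np.testing.assert_allclose(shifted.coef_, base.coef_, rtol=1e-9)

    def test_fixture_coefficients_round_to_reported_values(self, amylase_fit):
        # reported precisions: integers, 1 dp, 2 dp, 3 dp depending on term
        fitted = amylase_fit.coefficients_.to_numpy()
        decimals = [0, 0, 0, 1, 0, 1, 3, 1, 2, 2]
        for est, reported, dp in zip(fitted, REPORTED_COEFFICIENTS, decimals):
            assert round(est, dp) == pytest.approx(reported), (est, reported)

    def test_requires_full_rank_and_enough_runs(self, factors):
        design = generate_bbd(factors, center_points=3)
        X = design.actual
        with pytest.raises(ValueError, match="at least 10"):
            QuadraticResponseSurface().fit(X[:9], np.zeros(9))
        X_collapsed = X.copy()
        X_collapsed[:, 1] = X_collapsed[:, 0]  # ga duplicates cs
        with pytest.raises(np.linalg.LinAlgError):
            QuadraticResponseSurface().fit(X_collapsed, np.arange(15.0))

    def test_missing_responses_rejected(self, amylase_table):
        y = amylase_table.response("specific_activity").astype(float)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            QuadraticResponseSurface().fit(amylase_table.actual, y)


class TestPredict:
    def test_prediction_points(self, amylase_fit):
        # full-precision fit lands within 2 U/g of the published
        # (rounded-coefficient) prediction column
        assert amylase_fit.predict([2.5, 0.5, 6.0]) == pytest.approx(672, abs=2.5)
        assert amylase_fit.predict([3.0, 1.5, 16.0]) == pytest.approx(96, abs=2.5)
        assert amylase_fit.predict([2.5, 1.0, 16.0]) == pytest.approx(239, abs=2.5)

    def test_extrapolation_warns(self, amylase_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            amylase_fit.predict([3.5, 1.0, 16.0])

    def test_non_finite_rejected(self, amylase_fit):
        with pytest.raises(ValueError):
            amylase_fit.predict([np.nan, 1.0, 16.0])


class TestAnova:
    def test_fixture_anova_reproduces_reference_rows(self, amylase_fit):
        a = amylase_fit.anova().set_index("source")
        model = a.loc["model"]
        assert model["df"] == 9
        assert model["F"] == pytest.approx(29.25, abs=0.01)
        pe = a.loc["pure error"]
        assert pe["df"] == 2
        assert pe["ss"] == pytest.approx(2786, abs=0.5)
        lof = a.loc["lack-of-fit"]
        assert lof["df"] == 3
        assert lof["F"] == pytest.approx(0.89, abs=0.01)

    def test_ss_decomposition_closes(self, amylase_fit):
        a = amylase_fit.anova().set_index("source")
        sst = a.loc["total", "ss"]
        assert abs(a.loc["model", "ss"] + a.loc["error", "ss"] - sst) / sst < 1e-9
        err = a.loc["error", "ss"]
        assert a.loc["lack-of-fit", "ss"] + a.loc["pure error", "ss"] == pytest.approx(err)

    def test_adjusted_ss_matches_drop_term_refit_oracle(self, amylase_table, amylase_fit):
        """Oracle: literally refit without each term/group and difference the SSE."""
        y = amylase_table.response("specific_activity")
        M = _expand(amylase_table.actual)
        sse_full = ((y - M @ np.linalg.lstsq(M, y, rcond=None)[0]) ** 2).sum()

        def refit_without(cols):
            Mr = np.delete(M, cols, axis=1)
            resid = y - Mr @ np.linalg.lstsq(Mr, y, rcond=None)[0]
            return (resid ** 2).sum() - sse_full

        a = amylase_fit.anova().set_index("source")
        names = ["cs", "ga", "time", "cs^2", "ga^2", "time^2", "cs*ga", "cs*time", "ga*time"]
        for i, name in enumerate(names, start=1):
            assert a.loc[name, "ss"] == pytest.approx(refit_without([i]), rel=1e-8)
        for gname, cols in [("linear", [1, 2, 3]), ("square", [4, 5, 6]),
                            ("two-way interaction", [7, 8, 9])]:
            assert a.loc[gname, "ss"] == pytest.approx(refit_without(cols), rel=1e-8)

    def test_group_ss_exceed_sequential_possibility(self, amylase_fit):
        # adjusted group SS may legitimately sum to more than the model SS
        a = amylase_fit.anova().set_index("source")
        groups = a.loc[["linear", "square", "two-way interaction"], "ss"].sum()
        assert groups != pytest.approx(a.loc["model", "ss"], rel=1e-6)

    def test_no_replicates_means_no_lof_rows(self, factors, rng):
        design = generate_bbd(factors, center_points=1)  # 13 distinct points
        y = rng.normal(size=13) * 50 + 300
        model = QuadraticResponseSurface().fit(design.actual, y)
        sources = set(model.anova()["source"])
        assert "lack-of-fit" not in sources and "pure error" not in sources

    def test_anova_stats_invariant_under_affine_reparameterization(self, amylase_table):
        # per-factor affine recoding spans the same 10-term model space,
        # so overall fit statistics must not move (the piecewise center-
        # labelled coding is a different model space when levels are not
        # equidistant, and is deliberately not asserted here)
        y = amylase_table.response("specific_activity")
        X = amylase_table.actual
        mid = (X.max(axis=0) + X.min(axis=0)) / 2
        half = (X.max(axis=0) - X.min(axis=0)) / 2
        actual = QuadraticResponseSurface(unit_space="actual").fit(X, y)
        coded = QuadraticResponseSurface(unit_space="coded").fit((X - mid) / half, y)
        fa = actual.anova().set_index("source")
        fc = coded.anova().set_index("source")
        assert fa.loc["model", "F"] == pytest.approx(fc.loc["model", "F"], rel=1e-9)
        sa, sc = actual.summary(), coded.summary()
        assert sa.r_squared == pytest.approx(sc.r_squared, rel=1e-9)
        assert sa.adj_r_squared == pytest.approx(sc.adj_r_squared, rel=1e-9)
        assert sa.pred_r_squared == pytest.approx(sc.pred_r_squared, rel=1e-9)


class TestSummary:
    def test_fixture_summary_to_two_decimals(self, amylase_fit):
        s = amylase_fit.summary()
        assert round(s.r_squared, 2) == 0.98
        assert round(s.adj_r_squared, 2) == 0.95
        assert round(s.pred_r_squared, 2) == 0.81

    def test_summary_ordering(self, amylase_fit):
        s = amylase_fit.summary()
        assert s.pred_r_squared <= s.adj_r_squared <= s.r_squared

    def test_press_equals_literal_loo_refits(self, amylase_table, amylase_fit):
        """Oracle: 15 leave-one-out refits, squared prediction errors summed."""
        y = amylase_table.response("specific_activity")
        M = _expand(amylase_table.actual)
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            b = np.linalg.lstsq(M[keep], y[keep], rcond=None)[0]
            press += (y[i] - M[i] @ b) ** 2
        assert amylase_fit.summary().press == pytest.approx(press, rel=1e-8)

    def test_perfect_fit_on_noise_free_data(self, factors, rng):
        beta = rng.normal(size=10)
        design = generate_bbd(factors, center_points=3)
        y = _expand(design.actual) @ beta
        s = QuadraticResponseSurface().fit(design.actual, y).summary()
        assert s.r_squared == pytest.approx(1.0)
        assert s.press == pytest.approx(0.0, abs=1e-12)
        assert s.pred_r_squared == pytest.approx(1.0)


class TestOptimize:
    def test_fixture_optimum(self, amylase_fit, factor_box):
        opt = amylase_fit.optimize(factor_box, direction="maximize")
        assert opt.actual[1] == pytest.approx(0.5, abs=1e-6)   # ga at lower bound
        assert opt.actual[2] == pytest.approx(6.0, abs=1e-5)   # time at lower bound
        assert opt.actual[0] == pytest.approx(2.6, abs=0.1)    # cs
        assert opt.predicted == pytest.approx(675, rel=0.02)
        assert opt.boundary == ("interior", "at-low", "at-low")
        assert opt.classification == "boundary"

    def test_interior_maximum_found_exactly(self):
        # y = 100 - (x1-2.5)^2 - (x2-1)^2 - (x3-15)^2: stationary max inside box
        model = QuadraticResponseSurface()
        X = np.array(list(itertools.product([2.0, 2.5, 3.0], [0.5, 1.0, 1.5], [6.0, 15.0, 24.0])))
        y = 100 - (X[:, 0] - 2.5) ** 2 - (X[:, 1] - 1.0) ** 2 - (X[:, 2] - 15.0) ** 2
        model.fit(X, y)
        opt = model.optimize([(2, 3), (0.5, 1.5), (6, 24)])
        np.testing.assert_allclose(opt.actual, [2.5, 1.0, 15.0], atol=1e-6)
        assert opt.classification == "maximum"
        assert opt.predicted == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_quadratics_match_dense_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=10) * rng.choice([0.1, 1, 10], size=10)
        model = QuadraticResponseSurface()
        X = np.array(list(itertools.product([0.0, 0.5, 1.0], repeat=3)))
        model.fit(X, _expand(X) @ beta)
        bounds = [(0, 1)] * 3
        opt = model.optimize(bounds)
        axes = np.linspace(0, 1, 101)
        grid = np.array(list(itertools.product(axes, repeat=3)))
        vals = _expand(grid) @ beta
        best = grid[np.argmax(vals)]
        # optimum within one grid cell of the exhaustive argmax
        assert np.all(np.abs(np.array(opt.actual) - best) <= 0.01 + 1e-9)
        assert opt.predicted >= vals.max() - 1e-6

    def test_degenerate_quadratic_returns_boundary(self):
        model = QuadraticResponseSurface()
        X = np.array(list(itertools.product([0.0, 0.5, 1.0], repeat=3)))
        y = 1.0 + 2 * X[:, 0]  # purely linear surface
        model.fit(X, y)
        opt = model.optimize([(0, 1)] * 3)
        assert opt.classification == "boundary"
        assert opt.actual[0] == pytest.approx(1.0)
        assert opt.predicted == pytest.approx(3.0)

    def test_direction_validated(self, amylase_fit, factor_box):
        with pytest.raises(ValueError, match="direction"):
            amylase_fit.optimize(factor_box, direction="sideways")


class TestSurfaceGrid:
    def test_grid_values_equal_direct_predictions(self, amylase_fit):
        grid = amylase_fit.surface_grid(("cs", "ga"), {"time": 16.0}, resolution=5)
        assert len(grid) == 25
        for _, row in grid.iloc[[0, 4, 20, 24]].iterrows():
            assert row["predicted"] == pytest.approx(
                amylase_fit.predict([row["cs"], row["ga"], 16.0])
            )

    def test_single_node_grid(self, amylase_fit):
        grid = amylase_fit.surface_grid(("cs", "ga"), {"time": 16.0}, resolution=1)
        assert len(grid) == 1

    def test_cs_ridge_location(self, amylase_fit):
        # the cs-direction maximum at mid binding time sits at moderate cs
        grid = amylase_fit.surface_grid(("cs", "ga"), {"time": 16.0}, resolution=101)
        best = grid.loc[grid["predicted"].idxmax()]
        assert 2.0 <= best["cs"] <= 2.6

    def test_unknown_factor_name_rejected(self, amylase_fit):
        with pytest.raises(ValueError, match="unknown factor"):
            amylase_fit.surface_grid(("cs", "ph"), {"time": 16.0})


class TestParameterRecovery:
    def test_coefficients_within_three_se_at_default_noise(self):
        """Refits of noisy synthetic designs cover the truth at the ~3-SE level.

        Coverage is assessed per coefficient: each of the ten true values
        falls within 3 estimated standard errors in at least 95% of runs.
        """
        truth = TruthSurface()
        beta_true = np.asarray(truth.coefficients)
        n_sims = 500
        hits = np.zeros(10)
        for i in range(n_sims):
            reps = simulate_bbd_dataset(truth, seed=1000 + i)
            design = replicate_means_design(reps, truth.factors)
            # per-run means of 3 replicates: noise sd shrinks by sqrt(3)
            model = QuadraticResponseSurface().fit(
                design.actual, design.response("response")
            )
            est = np.concatenate([[model.intercept_], model.coef_])
            hits += np.abs(est - beta_true) <= 3 * model.standard_errors_
        assert np.all(hits / n_sims >= 0.95)
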