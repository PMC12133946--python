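import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lumigrow.design import ModelSpec, build_design
from lumigrow.effects import (
    ContrastDraws,
    difference_heatmap_table,
    endpoint_contrast,
    predicted_difference_curve,
    prob_greater,
    quantile_dots,
    rank_conditions,
    slope_difference_draws,
)
from tests.conftest import make_multi_condition_ds, synthetic_draws


@pytest.fixture(scope="module")
def design2(clean_two_arm_ds):
    return build_design(clean_two_arm_ds)


@pytest.fixture(scope="module")
def jittered_draws(design2):
    return synthetic_draws(
        design2,
        {"(Intercept)": 5.0, "time": 0.05, "cond[TRT]": 0.5, "time:cond[TRT]": 0.1},
        n_draws=600, jitter=0.02, seed=8,
    )


class TestSlopeDifference:
    def test_same_condition_is_zero(self, design2, jittered_draws):
        c = slope_difference_draws(jittered_draws, design2, "TRT", "TRT")
        assert np.all(c.values == 0.0)

    def test_reference_contrast_recovers_interaction(self, design2):
        draws = synthetic_draws(design2, {"time": 0.05, "time:cond[TRT]": 0.07})
        c = slope_difference_draws(draws, design2, "TRT", "CTRL")
        assert np.allclose(c.values, 0.07)

    def test_antisymmetry(self, design2, jittered_draws):
        ab = slope_difference_draws(jittered_draws, design2, "TRT", "CTRL")
        ba = slope_difference_draws(jittered_draws, design2, "CTRL", "TRT")
        assert np.allclose(ab.values, -ba.values)

    def test_matches_bruteforce_column_arithmetic(self, design2, jittered_draws):
        c = slope_difference_draws(jittered_draws, design2, "TRT", "CTRL")
        manual = jittered_draws.table["time:cond[TRT]"].to_numpy()
        assert np.allclose(c.values, manual)

    def test_spline_model_refused(self, clean_two_arm_ds):
        mid = float(np.median(clean_two_arm_ds.df["time"].unique()))
        d = build_design(clean_two_arm_ds, ModelSpec(spline_knots=(mid,)))
        draws = synthetic_draws(d, {})
        with pytest.raises(ValueError, match="spline"):
            slope_difference_draws(draws, d, "TRT", "CTRL")


class TestQuantileDots:
    def test_constant_draws(self):
        dots = quantile_dots(ContrastDraws("c", np.ones(500)), K=100)
        assert dots.K == 100 and np.all(dots.dots == 1.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            quantile_dots(ContrastDraws("c", np.arange(50)), K=100)

    def test_dots_match_normal_quantiles(self):
        rng = np.random.default_rng(0)
        dots = quantile_dots(ContrastDraws("c", rng.standard_normal(200_000)), K=100)
        expected = stats.norm.ppf(dots.probs)
        assert np.allclose(dots.dots, expected, atol=0.03)

    def test_nearest_with_K_equal_n_returns_sorted_draws(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(100)
        dots = quantile_dots(ContrastDraws("c", v), K=100, method="nearest")
        assert np.allclose(dots.dots, np.sort(v))

    def test_98_of_100_dots_reads_as_98_percent(self):
        # draw vector whose 2% lower tail sits below zero
        v = np.concatenate([np.full(20, -1.0), np.full(980, 1.0)])
        dots = quantile_dots(ContrastDraws("c", v), K=100)
        assert int(np.sum(dots.dots > 0)) == 98
        assert dots.fraction_above(0.0) == pytest.approx(0.98)


class TestProbGreater:
    def test_symmetric_draws_half(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(20_000)
        assert prob_greater(ContrastDraws("c", v)) == pytest.approx(0.5, abs=0.02)

    def test_all_above_threshold(self):
        assert prob_greater(ContrastDraws("c", np.arange(1, 10.0)), 0.0) == 1.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-2, 2))
    def test_monotone_nonincreasing_in_threshold(self, seed, t):
        rng = np.random.default_rng(seed)
        c = ContrastDraws("c", rng.standard_normal(500))
        assert prob_greater(c, t) >= prob_greater(c, t + 0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-1.5, 1.5))
    def test_agrees_with_dot_fraction_within_one_dot(self, seed, t):
        rng = np.random.default_rng(seed)
        c = ContrastDraws("c", rng.normal(0.3, 1.0, 2000))
        dots = quantile_dots(c, K=100)
        assert abs(prob_greater(c, t) - dots.fraction_above(t)) <= 0.01 + 1e-12


class TestDifferenceCurves:
    def test_same_condition_zero_bands(self, design2, jittered_draws):
        grid = np.linspace(0, 60, 7)
        curve = predicted_difference_curve(jittered_draws, design2, "TRT", "TRT", grid)
        assert np.allclose(curve.center, 0.0)
        for lev in curve.levels:
            assert np.allclose(curve.lower[lev], 0.0)
            assert np.allclose(curve.upper[lev], 0.0)

    def test_bands_are_nested(self, design2, jittered_draws):
        grid = np.linspace(0, 60, 7)
        curve = predicted_difference_curve(jittered_draws, design2, "TRT", "CTRL", grid)
        assert np.all(curve.lower[0.95] <= curve.lower[0.25])
        assert np.all(curve.upper[0.25] <= curve.upper[0.95])
        assert np.all((curve.lower[0.25] <= curve.center) & (curve.center <= curve.upper[0.25]))

    def test_center_is_bruteforce_median(self, design2, jittered_draws):
        grid = [0.0, 30.0, 60.0]
        curve = predicted_difference_curve(jittered_draws, design2, "TRT", "CTRL", grid)
        X1 = design2.population_matrix(["TRT"], grid)
        X0 = design2.population_matrix(["CTRL"], grid)
        B = jittered_draws.table[design2.labels].to_numpy()
        diff = B @ (X1 - X0).T
        assert np.allclose(curve.center, np.median(diff, axis=0))

    def test_extrapolation_warns(self, design2, jittered_draws):
        with pytest.warns(UserWarning, match="extrapolat"):
            predicted_difference_curve(jittered_draws, design2, "TRT", "CTRL", [0.0, 999.0])


class TestEndpointContrast:
    def test_equal_conditions_zero(self, design2, jittered_draws):
        c = endpoint_contrast(jittered_draws, design2, "TRT", "TRT", 0.0, 60.0)
        assert np.allclose(c.values, 0.0)

    def test_pure_interaction_gives_plus_one_at_endpoint(self, design2):
        # slope excess of 1/60 per day accumulates to +1 over [0, 60] with equal baselines
        draws = synthetic_draws(design2, {"time:cond[TRT]": 1.0 / 60.0})
        c = endpoint_contrast(draws, design2, "TRT", "CTRL", 0.0, 60.0)
        assert np.allclose(c.values, 1.0)

    def test_baseline_shift_cancels(self, design2):
        # a pure baseline offset is removed by the t0 normalization
        draws = synthetic_draws(design2, {"cond[TRT]": 0.7})
        c = endpoint_contrast(draws, design2, "TRT", "CTRL", 0.0, 60.0)
        assert np.allclose(c.values, 0.0)

    def test_matches_bruteforce_four_terms(self, design2, jittered_draws):
        t0, t1 = 0.0, 60.0
        c = endpoint_contrast(jittered_draws, design2, "TRT", "CTRL", t0, t1)
        B = jittered_draws.table[design2.labels].to_numpy()
        m = lambda cond, t: B @ design2.row_for(cond, t)
        manual = (m("TRT", t1) - m("CTRL", t1)) - (m("TRT", t0) - m("CTRL", t0))
        assert np.allclose(c.values, manual)

    def test_time_order_enforced(self, design2, jittered_draws):
        with pytest.raises(ValueError):
            endpoint_contrast(jittered_draws, design2, "TRT", "CTRL", 60.0, 0.0)


@pytest.fixture(scope="module")
def screen():
    ds = make_multi_condition_ds(25, seed=4, n_units=2)
    design = build_design(ds, ModelSpec(reference="C00"))
    rng = np.random.default_rng(0)
    coef = {"time": 0.02}
    for c in design.conditions[1:]:
        coef[f"time:cond[{c}]"] = float(rng.normal(0, 0.01))
    draws = synthetic_draws(design, coef, n_draws=400, jitter=0.01, seed=5)
    return ds, design, draws


class TestScreenSummaries:
    def test_ranking_has_24_sorted_rows(self, screen):
        _, design, draws = screen
        tab = rank_conditions(draws, design, "C00", 0.0, 60.0)
        assert len(tab) == 24
        assert list(tab["mean"]) == sorted(tab["mean"])
        assert tab["prob_gt_0"].between(0, 1).all()

    def test_heatmap_dims_and_consistency(self, screen):
        _, design, draws = screen
        grid = np.linspace(0.0, 60.0, 5)
        heat = difference_heatmap_table(draws, design, "C00", grid)
        assert len(heat) == 24 * 5
        # cells are posterior means of the same differenced predictions
        sub = heat[heat["condition"] == "C05"]
        X1 = design.population_matrix(["C05"], grid)
        X0 = design.population_matrix(["C00"], grid)
        B = draws.table[design.labels].to_numpy()
        manual = (B @ (X1 - X0).T).mean(axis=0)
        assert np.allclose(sub["mean_difference"].to_numpy(), manual)
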