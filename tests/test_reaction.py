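import numpy as np
import pandas as pd
import pytest

from crowdkappa.errors import ValidationError
from crowdkappa.reaction import (
    item_rt_summary,
    log_rt,
    rt_quadratic_fit,
    rt_variability_summary,
)
from crowdkappa.simulate import SimulationConfig, simulate_study

from conftest import make_table


class TestLogRT:
    def test_known_values(self):
        assert log_rt(0.0) == 0.0
        assert log_rt(np.e - 1) == pytest.approx(1.0, abs=1e-12)
        assert log_rt(2.5) == pytest.approx(np.log(3.5), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_rt(-0.1)

    def test_strictly_increasing(self):
        xs = np.linspace(0, 10, 50)
        assert (np.diff(log_rt(xs)) > 0).all()


class TestItemSummary:
    def test_single_rating(self, taxonomy):
        table = make_table([("u1", "i1", "dots", 1, 2.5)], taxonomy=taxonomy)
        items = item_rt_summary(table, "dots")
        assert items["mean_log_rt"].iloc[0] == pytest.approx(np.log(3.5))
        assert items["avg_response"].iloc[0] == 1.0

    def test_two_rater_means(self, taxonomy):
        # RTs 0 and e-1 give log-RTs 0 and 1; responses 1 and 0
        df = pd.DataFrame(
            [
                ["u1", "i1", "dots", 1, 0.0, "crowd"],
                ["u2", "i1", "dots", 0, np.e - 1, "crowd"],
            ],
            columns=["rater_id", "image_id", "feature", "present",
                     "reaction_time_s", "cohort"],
        )
        from crowdkappa.io_core import RatingTable

        table = RatingTable(df=df, level="superfeature")  # bypass rt>0 check
        items = item_rt_summary(table, "dots")
        assert items["mean_log_rt"].iloc[0] == pytest.approx(0.5)
        assert items["avg_response"].iloc[0] == pytest.approx(0.5)

    def test_untimed_items_dropped_with_warning(self, taxonomy):
        table = make_table(
            [("u1", "i1", "dots", 1, 2.0), ("u1", "i2", "dots", 0)],
            taxonomy=taxonomy,
        )
        with pytest.warns(UserWarning, match="without timed"):
            items = item_rt_summary(table, "dots")
        assert list(items["image_id"]) == ["i1"]

    def test_all_untimed_rejected(self, taxonomy):
        table = make_table([("u1", "i1", "dots", 1)], taxonomy=taxonomy)
        with pytest.raises(ValidationError, match="timed"):
            item_rt_summary(table, "dots")

    def test_order_invariant(self, taxonomy):
        rows = [("u%d" % k, "i1", "dots", k % 2, 1.0 + k) for k in range(6)]
        a = item_rt_summary(make_table(rows, taxonomy=taxonomy), "dots")
        b = item_rt_summary(make_table(rows[::-1], taxonomy=taxonomy), "dots")
        pd.testing.assert_frame_equal(a, b)


def quad_items(coeffs, xs):
    a0, a1, a2 = coeffs
    return pd.DataFrame(
        {"image_id": [f"i{k}" for k in range(len(xs))],
         "avg_response": xs,
         "mean_log_rt": a0 + a1 * np.asarray(xs) + a2 * np.asarray(xs) ** 2}
    )


class TestQuadraticFit:
    def test_noise_free_recovery(self):
        items = quad_items((1.0, 0.5, -2.0), [0, 0.25, 0.5, 0.75, 1.0])
        fit = rt_quadratic_fit(items)
        a0, a1, a2 = fit.uncentered_coefficients
        assert a0 == pytest.approx(1.0, abs=1e-10)
        assert a1 == pytest.approx(0.5, abs=1e-10)
        assert a2 == pytest.approx(-2.0, abs=1e-10)

    def test_center_zero_matches_raw_basis(self):
        items = quad_items((0.3, -0.7, 1.2), [0, 0.2, 0.4, 0.9])
        fit = rt_quadratic_fit(items, center=0.0)
        assert fit.params == pytest.approx([0.3, -0.7, 1.2], abs=1e-10)

    def test_constant_response_yields_zero_slopes_and_t(self):
        items = quad_items((2.0, 0.0, 0.0), [0, 0.25, 0.5, 0.75, 1.0])
        fit = rt_quadratic_fit(items)
        assert fit.b1 == pytest.approx(0.0, abs=1e-10)
        assert fit.b2 == pytest.approx(0.0, abs=1e-10)
        assert fit.tvalues[1] == 0.0 and fit.tvalues[2] == 0.0
        assert fit.pvalues[1] == 1.0

    def test_residual_df_and_orthogonality(self):
        rng = np.random.default_rng(5)
        xs = rng.random(40)
        items = quad_items((1.0, -0.5, -1.0), xs)
        items["mean_log_rt"] += rng.normal(0, 0.2, size=40)
        fit = rt_quadratic_fit(items)
        assert fit.df_resid == 40 - 3
        t = xs - fit.center
        X = np.column_stack([np.ones(40), t, t * t])
        resid = items["mean_log_rt"].to_numpy() - fit.predict(xs)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_matches_closed_form_normal_equations(self):
        """Independent check of coefficients, SEs and p-values against a
        direct normal-equations computation."""
        from scipy import stats as sps

        rng = np.random.default_rng(17)
        xs = rng.random(60)
        items = quad_items((0.8, -0.6, -0.9), xs)
        items["mean_log_rt"] += rng.normal(0, 0.15, size=60)
        fit = rt_quadratic_fit(items)
        t = xs - 0.5
        X = np.column_stack([np.ones(60), t, t * t])
        y = items["mean_log_rt"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (60 - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert fit.params == pytest.approx(beta, abs=1e-8)
        assert fit.bse == pytest.approx(se, abs=1e-8)
        assert fit.pvalues == pytest.approx(
            2 * sps.t.sf(np.abs(beta / se), 57), abs=1e-10
        )

    def test_weighted_option(self):
        items = quad_items((1.0, -0.5, -1.0), [0.1, 0.3, 0.5, 0.7, 0.9])
        items["n_raters"] = [1, 5, 10, 5, 1]
        fit = rt_quadratic_fit(items, weighted=True)
        assert fit.n_items == 5
        with pytest.raises(ValidationError, match="n_raters"):
            rt_quadratic_fit(items.drop(columns="n_raters"), weighted=True)

    def test_too_few_items_or_rank_deficiency_rejected(self):
        with pytest.raises(ValidationError, match="at least 4"):
            rt_quadratic_fit(quad_items((1, 0, 0), [0.1, 0.5, 0.9]))
        degenerate = quad_items((1, 0, 0), [0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValidationError, match="rank-deficient"):
            rt_quadratic_fit(degenerate)

    def test_vertex_near_indecision_without_presence_effect(self):
        """With no presence speed-up the fitted peak sits near the point
        of indecision."""
        cfg = SimulationConfig(
            superfeatures=("dots",), rt_beta_p=0.0, rt_beta_u=0.3,
        )
        ds = simulate_study(cfg, seed=21)
        items = item_rt_summary(ds.ratings.subset(cohort="crowd"), "dots")
        fit = rt_quadratic_fit(items)
        assert fit.b2 < 0
        assert abs(fit.vertex - 0.5) < 0.1


class TestVariability:
    def test_identical_users_give_zero_iqrs(self, taxonomy):
        rows = [(u, f"i{k}", "dots", 1, 2.0) for u in ("a", "b") for k in range(3)]
        out = rt_variability_summary(make_table(rows, taxonomy=taxonomy))
        assert out["across_user_iqr"] == 0.0
        assert out["within_user_iqr"] == 0.0

    def test_pure_between_user_spread(self, taxonomy):
        rows = [("a", f"i{k}", "dots", 1, 1.0) for k in range(3)]
        rows += [("b", f"i{k}", "dots", 1, 4.0) for k in range(3)]
        out = rt_variability_summary(make_table(rows, taxonomy=taxonomy))
        assert out["within_user_iqr"] == 0.0
        assert out["across_user_iqr"] > 0.0
        assert not out["within_exceeds_across"]

    def test_default_simulation_pattern(self, small_dataset):
        out = rt_variability_summary(small_dataset.ratings.subset(cohort="crowd"))
        assert out["across_user_iqr"] > 0
        assert out["within_user_iqr"] > 0
        assert out["within_exceeds_across"]

    def test_insufficient_data_rejected(self, taxonomy):
        table = make_table([("a", "i1", "dots", 1, 2.0)], taxonomy=taxonomy)
        with pytest.raises(ValidationError):
            rt_variability_summary(table)
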