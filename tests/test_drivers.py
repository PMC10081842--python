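"""Spatial-autocorrelation covariate, sequential/partial-SS models, battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import hadamard

from esens.drivers import (DriverDesign, auto_covariate, convergence_bootstrap,
                           driver_anova, driver_battery, interaction_model,
                           transform_metric)
from esens.synthetic import CountrySpec, ModelSpec, WorldSpec
from esens.pipeline import simulate_plot_accuracy


class TestAutoCovariate:
    def test_isolated_points_fall_back_to_global_mean(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        D = np.array([0.2, 0.5, 0.8])
        np.testing.assert_allclose(auto_covariate(pts, D, max_range=5.0), 0.5)

    def test_coincident_points_see_each_other(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0]])
        D = np.array([0.3, 0.9])
        np.testing.assert_allclose(auto_covariate(pts, D), [0.9, 0.3])

    def test_collinear_hand_computed_weights(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        D = np.array([0.0, 1.0, 0.0])
        auto = auto_covariate(pts, D, max_range=5.0)
        # middle point: both neighbours have D = 0
        assert auto[1] == pytest.approx(0.0)
        # outer points: weights 1/1 and 1/2 on D = 1 and 0
        assert auto[0] == pytest.approx((1.0 * 1.0) / 1.5)
        assert auto[2] == pytest.approx((1.0 * 1.0) / 1.5)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auto_covariate(np.array([[0.0, 0.0]]), np.array([0.5]))


class TestTransformMetric:
    def test_arcsine_endpoints_and_midpoint(self):
        out = transform_metric(np.array([0.0, 0.5, 1.0]), "arcsine", scale=1.0)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.pi / 4)
        assert out[2] == pytest.approx(np.pi / 2)

    def test_percentage_scale_inferred(self):
        out = transform_metric(np.array([25.0, 100.0]), "arcsine")
        assert out[1] == pytest.approx(np.pi / 2)

    def test_log10(self):
        assert transform_metric(np.array([1000.0]), "log10")[0] == pytest.approx(3.0)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            transform_metric(np.array([-1.0, 5.0]), "log10")
        with pytest.raises(ValueError):
            transform_metric(np.array([0.5, 1.5]), "arcsine", scale=1.0)


def _normal_equations_oracle(y, auto, metric):
    """Sequential-SS F values from explicit normal equations."""
    def rss(cols):
        X = np.column_stack([np.ones_like(y)] + cols)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    rss0, rss1, rss2 = rss([]), rss([auto]), rss([auto, metric])
    df = len(y) - 3
    ms = rss2 / df
    return (rss0 - rss1) / ms, (rss1 - rss2) / ms


class TestDriverAnova:
    def _design(self, seed=0, n=30, coupled=False):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 2))
        metric = rng.normal(size=n)
        D = 0.7 + 0.05 * rng.normal(size=n) + (0.1 * metric if coupled else 0.0)
        return DriverDesign(np.clip(D, 0, 1), pts, metric)

    def test_matches_normal_equations_oracle(self):
        d = self._design(seed=4, n=30)
        res = driver_anova(d)
        F_auto, F_metric = _normal_equations_oracle(d.D_per_point, d.auto, d.metric)
        assert res.factor("Auto").F == pytest.approx(F_auto, abs=1e-8)
        assert res.factor("Metric").F == pytest.approx(F_metric, abs=1e-8)

    def test_matches_statsmodels_type1_anova(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        d = self._design(seed=7, n=40)
        df = pd.DataFrame({"D": d.D_per_point, "auto": d.auto, "metric": d.metric})
        tab = sm.stats.anova_lm(ols("D ~ auto + metric", df).fit(), typ=1)
        res = driver_anova(d)
        assert res.factor("Auto").F == pytest.approx(tab.loc["auto", "F"], rel=1e-10)
        assert res.factor("Metric").F == pytest.approx(tab.loc["metric", "F"], rel=1e-10)
        assert res.factor("Metric").p_two == pytest.approx(tab.loc["metric", "PR(>F)"],
                                                           rel=1e-9)

    def test_perfect_predictor_has_huge_F(self):
        d = self._design(seed=1, n=30)
        d2 = DriverDesign(d.D_per_point, d.centroids, d.D_per_point, auto=d.auto)
        res = driver_anova(d2)
        assert res.factor("Metric").F > 1e4
        assert res.factor("Metric").p_one < 1e-10

    def test_null_metric_rejection_rate_near_alpha(self):
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            res = driver_anova(self._design(seed=s, n=40))
            hits += res.factor("Metric").p_one < 0.05
        assert hits / n_rep < 1.5 * 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_one_sided_p_follows_slope_sign(self):
        d = self._design(seed=3, n=30, coupled=True)
        res = driver_anova(d)
        f = res.factor("Metric")
        assert f.coef > 0
        assert f.p_one == pytest.approx(f.p_two / 2)
        assert f.F_signed > 0

    def test_constant_covariate_rejected(self):
        d = self._design(seed=0, n=30)
        with pytest.raises(ValueError, match="constant"):
            driver_anova(DriverDesign(d.D_per_point, d.centroids,
                                      np.zeros(30), auto=d.auto))


class TestInteractionModel:
    def test_orthogonal_design_type1_equals_type3(self):
        H = hadamard(16).astype(float)
        rng = np.random.default_rng(5)
        # with Sylvester ordering H_i * H_j = H_(i xor j): g*e = H_1, so the
        # auto column must avoid index 1 to keep the design full-rank
        auto, g, e = H[:, 4], H[:, 2], H[:, 3]
        y = 0.5 + 0.1 * g + 0.05 * e + 0.02 * rng.normal(size=16)
        res3 = interaction_model(y, np.zeros((16, 2)), g, e, auto=auto,
                                 gdp_transform="none", equality_transform="none")
        # sequential SS oracle for the same ordering (orthogonal => equal)
        def rss(cols):
            X = np.column_stack([np.ones(16)] + cols)
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            r = y - X @ b
            return r @ r

        seq_g = rss([auto]) - rss([auto, g])
        seq_e = rss([auto, g]) - rss([auto, g, e])
        assert res3.factor("GDP").ss == pytest.approx(seq_g, abs=1e-10)
        assert res3.factor("Equality").ss == pytest.approx(seq_e, abs=1e-10)

    def test_null_interaction_rejection_rate_nominal(self):
        hits = 0
        n_rep = 150
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            n = 60
            g = rng.normal(size=n)
            e = rng.normal(size=n)
            y = np.clip(0.6 + 0.1 * g + 0.1 * e + 0.1 * rng.normal(size=n), 0, 1)
            res = interaction_model(y, rng.uniform(0, 10, (n, 2)), g, e,
                                    gdp_transform="none", equality_transform="none")
            hits += res.factor("GDPxEquality").p_two < 0.05
        assert hits / n_rep < 0.1

    def test_pure_interaction_detected_mains_not(self):
        found_inter, found_mains = 0, 0
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            n = 80
            g = rng.choice([-1.0, 1.0], n)
            e = rng.choice([-1.0, 1.0], n)
            y = np.clip(0.5 + 0.15 * g * e + 0.05 * rng.normal(size=n), 0, 1)
            res = interaction_model(y, rng.uniform(0, 10, (n, 2)), g, e,
                                    gdp_transform="none", equality_transform="none")
            found_inter += res.factor("GDPxEquality").p_two < 0.05
            found_mains += (res.factor("GDP").p_two < 0.05
                            or res.factor("Equality").p_two < 0.05)
        assert found_inter / 40 > 0.9
        assert found_mains / 40 < 0.4


class TestConvergenceBootstrap:
    def _design(self, n, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 2))
        metric = rng.normal(size=n)
        D = np.clip(0.7 + 0.08 * rng.normal(size=n), 0, 1)
        return DriverDesign(D, pts, metric)

    def test_degenerate_subsampling_equals_single_fit(self):
        d = self._design(40)
        single = driver_anova(d)

        def fit(idx):
            return driver_anova(DriverDesign(d.D_per_point[idx], d.centroids[idx],
                                             d.metric[idx], auto=d.auto[idx]))

        res = convergence_bootstrap(fit, d.D_per_point, n_sample=40, patience=25)
        assert res.converged
        assert res.n_iterations == 26  # minimum possible with 25-streak rule
        assert res.factor("Metric").F == pytest.approx(single.factor("Metric").F)

    def test_deterministic_across_reruns(self):
        d = self._design(80, seed=3)

        def fit(idx):
            return driver_anova(DriverDesign(d.D_per_point[idx], d.centroids[idx],
                                             d.metric[idx], auto=d.auto[idx]))

        a = convergence_bootstrap(fit, d.D_per_point, n_sample=40, seed=5)
        b = convergence_bootstrap(fit, d.D_per_point, n_sample=40, seed=5)
        assert a.factor("Metric").F == b.factor("Metric").F
        assert a.n_iterations == b.n_iterations

    def test_insufficient_points_rejected(self):
        d = self._design(20)
        with pytest.raises(ValueError):
            convergence_bootstrap(lambda idx: driver_anova(d), d.D_per_point,
                                  n_sample=50)


@pytest.fixture(scope="module")
def null_world():
    world = WorldSpec(grid_rows=32, grid_cols=32, correlation_length=6, seed=0)
    specs = [ModelSpec(f"m{i}", noise_sd=0.3) for i in range(5)]
    cspec = CountrySpec(n_countries=40, accuracy_coupling=0.0)
    return simulate_plot_accuracy(world, specs, cspec, seed=12)


class TestDriverBattery:
    def test_battery_has_exactly_eight_tests(self, null_world):
        D, countries, _ = null_world
        table = driver_battery(D, countries.centroids, countries.metrics)
        assert len(table) == 8
        assert (table["model"] == "single").sum() == 5
        assert (table["model"] == "interaction").sum() == 3

    def test_strongly_coupled_metric_flagged(self):
        found = 0
        for s in range(15):
            world = WorldSpec(grid_rows=32, grid_cols=32, correlation_length=6,
                              seed=s)
            specs = [ModelSpec(f"m{i}", noise_sd=0.3) for i in range(5)]
            cspec = CountrySpec(n_countries=120, accuracy_coupling=-0.9,
                                coupled_metric="hdi")
            D, countries, _ = simulate_plot_accuracy(world, specs, cspec, seed=s)
            table = driver_battery(D, countries.centroids, countries.metrics)
            row = table[table["term"] == "hdi"].iloc[0]
            found += bool(row["significant"])
        assert found / 15 >= 0.8

    def test_spatially_clustered_noise_drives_auto_term(self):
        """b1 on Auto is positive on clustered-noise worlds, not on iid ones."""
        def auto_signed_F(s, clustered):
            ncl = 5.0 if clustered else 0.0
            world = WorldSpec(grid_rows=32, grid_cols=32, correlation_length=6,
                              seed=s)
            specs = [ModelSpec(f"m{i}", noise_sd=0.4,
                               noise_correlation_length=ncl) for i in range(5)]
            cspec = CountrySpec(n_countries=150, accuracy_coupling=0.0)
            D, countries, _ = simulate_plot_accuracy(world, specs, cspec, seed=s)
            d = DriverDesign(D, countries.centroids,
                             countries.metrics["hdi"].to_numpy())
            return driver_anova(d).factor("Auto")

        clustered = [auto_signed_F(s, True) for s in range(12)]
        iid = [auto_signed_F(s, False) for s in range(12)]
        sig_clustered = sum(f.F_signed > 0 and f.p_two < 0.05 for f in clustered)
        sig_iid = sum(f.p_two < 0.05 for f in iid)
        assert sig_clustered >= 8
        assert sig_iid <= 3
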