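"""Accuracy scoring, bootstrap comparison and multiple-testing correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esens.ensemble import build_ensemble, renormalize_full_range, winsorise_raster
from esens.grids import ModelStack
from esens.synthetic import (ModelSpec, WorldSpec, gen_model_outputs,
                             gen_true_surface, gen_validation)
from esens.validation import (PredictionVector, bootstrap_compare,
                              deviance_accuracy, extract_predictions,
                              hochberg_correct, improvement_vs_random_model,
                              proxy_and_bundle_accuracy, score_predictor)

from conftest import make_raster


def deviance_oracle(x, y):
    """Brute-force loop implementation of the inverse of deviance."""
    total = 0.0
    for xi, yi in zip(x, y):
        total += abs(xi - yi)
    return 1.0 - total / len(x)


class TestDevianceAccuracy:
    def test_perfect_agreement(self):
        x = np.array([0.1, 0.5, 0.9])
        res = deviance_accuracy(x, PredictionVector("self", x.copy()))
        assert res.overall == 1.0
        np.testing.assert_array_equal(res.per_point, 1.0)

    def test_maximal_deviance(self):
        res = deviance_accuracy(np.array([0.0, 0.0]),
                                PredictionVector("anti", np.array([1.0, 1.0])))
        assert res.overall == 0.0

    def test_worked_example(self):
        res = deviance_accuracy(np.array([0.5, 0.5]),
                                PredictionVector("p", np.array([0.4, 0.7])))
        assert res.overall == pytest.approx(0.85)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(2, 60)
            x, y = rng.random(n), rng.random(n)
            res = deviance_accuracy(x, PredictionVector("p", y))
            assert res.overall == pytest.approx(deviance_oracle(x, y), abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            deviance_accuracy(np.array([0.0, 2.0]),
                              PredictionVector("p", np.array([0.0, 0.5])))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deviance_accuracy(np.array([0.0, 1.0]),
                              PredictionVector("p", np.array([0.5])))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_joint_permutation(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(20), rng.random(20)
        perm = rng.permutation(20)
        a = deviance_accuracy(x, PredictionVector("p", y))
        b = deviance_accuracy(x[perm], PredictionVector("p", y[perm]))
        assert a.overall == pytest.approx(b.overall, abs=1e-14)


class TestExtraction:
    def test_point_value_reads_containing_cell(self):
        truth = gen_true_surface(WorldSpec(grid_rows=10, grid_cols=10, seed=3))
        vs = gen_validation(truth, "point", 15, obs_noise_sd=0.0, seed=4)
        pred = extract_predictions(truth, vs, "point_value")
        np.testing.assert_allclose(pred.values, vs.observed)

    def test_zero_radius_degenerates_to_containing_cell(self):
        truth = gen_true_surface(WorldSpec(grid_rows=10, grid_cols=10, seed=3))
        vs = gen_validation(truth, "point", 10, obs_noise_sd=0.0, seed=4)
        a = extract_predictions(truth, vs, "max_within_radius", radius=0.0)
        b = extract_predictions(truth, vs, "point_value")
        np.testing.assert_allclose(a.values, b.values)

    def test_max_within_radius_matches_brute_force(self):
        rng = np.random.default_rng(5)
        truth = gen_true_surface(WorldSpec(grid_rows=20, grid_cols=20,
                                           cell_size=1.0, seed=6))
        vs = gen_validation(truth, "point", 25, obs_noise_sd=0.0, seed=7)
        radius = 2.5
        pred = extract_predictions(truth, vs, "max_within_radius", radius=radius)
        xx, yy = truth.grid.center_grids()
        for i, u in enumerate(vs.units):
            best = -np.inf
            for r in range(20):
                for c in range(20):
                    d = np.hypot(xx[r, c] - u.centroid[0], yy[r, c] - u.centroid[1])
                    if d <= radius:
                        best = max(best, truth.values[r, c])
            assert pred.values[i] == pytest.approx(best)

    def test_max_within_radius_clipped_to_catchment(self):
        truth = gen_true_surface(WorldSpec(grid_rows=12, grid_cols=12, seed=8))
        vs = gen_validation(truth, "catchment", 4, obs_noise_sd=0.0, seed=9)
        pred = extract_predictions(truth, vs, "max_within_radius", radius=100.0)
        for i, u in enumerate(vs.units):
            inside_max = truth.values.ravel()[np.asarray(u.cells)].max()
            assert pred.values[i] == pytest.approx(inside_max)

    def test_unit_without_data_is_missing(self):
        world = gen_true_surface(WorldSpec(grid_rows=8, grid_cols=8, seed=1))
        vs = gen_validation(world, "point", 5, obs_noise_sd=0.0, seed=2)
        holed = world.with_values(world.values, np.ones(world.grid.shape, bool))
        pred = extract_predictions(holed, vs, "point_value")
        assert pred.n_missing == 5


class TestHochberg:
    def test_no_rejections_for_large_p(self):
        flags = hochberg_correct(np.array([0.2, 0.4, 0.6]), alpha=0.05)
        assert not flags.any()

    def test_step_up_worked_example(self):
        flags = hochberg_correct(np.array([0.01, 0.02, 0.04, 0.2]),
                                 alpha=0.05, m=4)
        np.testing.assert_array_equal(flags, [True, False, False, False])

    def test_all_zero_p_all_rejected(self):
        assert hochberg_correct(np.zeros(5), alpha=0.05).all()

    def test_matches_statsmodels_for_full_family(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(30):
            p = rng.random(6)
            mine = hochberg_correct(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="simes-hochberg")[0]
            np.testing.assert_array_equal(mine, ref)

    def test_family_larger_than_vector_is_stricter(self):
        p = np.array([0.012, 0.3])
        assert hochberg_correct(p, alpha=0.05, m=2)[0]
        assert not hochberg_correct(p, alpha=0.05, m=8)[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            hochberg_correct(np.array([0.5, 1.5]))


class TestBootstrapCompare:
    def test_identical_predictors_show_no_difference(self):
        rng = np.random.default_rng(1)
        x = rng.random(60)
        y = rng.random(60)
        preds = [PredictionVector("a", y), PredictionVector("b", y.copy())]
        comp = bootstrap_compare(preds, x, n_runs=50, sample_rule=("fixed", 30),
                                 seed=3)
        assert comp.pairs["mean_diff"].iloc[0] == 0.0
        assert not comp.pairs["significant"].iloc[0]

    def test_truthful_predictor_dominates_noisy_one(self):
        rng = np.random.default_rng(2)
        x = rng.random(80)
        noisy = np.clip(x + rng.normal(0, 0.4, 80), 0, 1)
        preds = [PredictionVector("truthful", x.copy()),
                 PredictionVector("noisy", noisy)]
        comp = bootstrap_compare(preds, x, n_runs=200, sample_rule=("fixed", 40),
                                 seed=4, normalize=False)
        row = comp.pairs.iloc[0]
        assert row["mean_diff"] > 0
        assert row["significant"]

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        x = rng.random(50)
        preds = [PredictionVector("a", rng.random(50)),
                 PredictionVector("b", rng.random(50))]
        c1 = bootstrap_compare(preds, x, n_runs=40, seed=9)
        c2 = bootstrap_compare(preds, x, n_runs=40, seed=9)
        np.testing.assert_array_equal(c1.run_accuracies, c2.run_accuracies)

    def test_listwise_dropping_of_missing_units(self):
        x = np.linspace(0, 1, 30)
        y1 = x.copy()
        y2 = x.copy()
        y2[3] = np.nan
        comp = bootstrap_compare([PredictionVector("a", y1), PredictionVector("b", y2)],
                                 x, n_runs=10, sample_rule=("fixed", 10), seed=0)
        assert comp.dropped_units == 1


class TestImprovement:
    def test_difference_in_percentage_points(self):
        ens = deviance_accuracy(np.array([0.5, 0.5]),
                                PredictionVector("e", np.array([0.3, 0.3])))
        models = [
            deviance_accuracy(np.array([0.5, 0.5]),
                              PredictionVector(f"m{i}", np.array([v, v])))
            for i, v in enumerate([0.2, 0.16, 0.1])
        ]
        # ensemble D = 0.8; model Ds = 0.7, 0.66, 0.6 -> median 0.66
        assert improvement_vs_random_model(ens, models) == pytest.approx(14.0)

    def test_zero_when_equal_to_median_model(self):
        x = np.array([0.2, 0.8])
        acc = deviance_accuracy(x, PredictionVector("p", x.copy()))
        assert improvement_vs_random_model(acc, [acc, acc, acc]) == 0.0

    def test_negative_allowed(self):
        x = np.array([0.5, 0.5])
        worse = deviance_accuracy(x, PredictionVector("e", np.array([0.0, 1.0])))
        better = deviance_accuracy(x, PredictionVector("m", x.copy()))
        assert improvement_vs_random_model(worse, [better, better]) < 0


class TestProxyAndBundle:
    def _service(self, truth, seed):
        stack = gen_model_outputs(truth, [ModelSpec(f"m{seed}", noise_sd=0.05)],
                                  seed=seed)
        norm = ModelStack({m: winsorise_raster(stack[m])[0] for m in stack.ids})
        return renormalize_full_range(build_ensemble(norm, "median"))

    def test_self_proxy_equals_own_accuracy(self):
        truth = gen_true_surface(WorldSpec(grid_rows=16, grid_cols=16, seed=1))
        ens = self._service(truth, 2)
        vs = gen_validation(truth, "point", 40, obs_noise_sd=0.0, seed=3)
        results = proxy_and_bundle_accuracy({"self": ens, "other": ens}, vs,
                                            "point_value")
        direct = score_predictor(ens.values, vs, "point_value")
        assert results["self"].overall == pytest.approx(direct.overall)

    def test_bundle_of_identical_ensembles_matches_member(self):
        truth = gen_true_surface(WorldSpec(grid_rows=16, grid_cols=16, seed=1))
        ens = self._service(truth, 2)
        vs = gen_validation(truth, "point", 40, obs_noise_sd=0.0, seed=3)
        results = proxy_and_bundle_accuracy({"a": ens, "b": ens}, vs, "point_value")
        assert results["bundle"].overall == pytest.approx(results["a"].overall,
                                                          abs=1e-12)

    def test_anticorrelated_service_is_a_poor_proxy(self):
        w = WorldSpec(grid_rows=16, grid_cols=16, seed=4)
        truth1 = gen_true_surface(w)
        truth2 = truth1.with_values(1.0 - truth1.values)
        ens1 = self._service(truth1, 5)
        ens2 = self._service(truth2, 6)
        vs = gen_validation(truth1, "point", 60, obs_noise_sd=0.0, seed=7)
        results = proxy_and_bundle_accuracy({"own": ens1, "anti": ens2}, vs,
                                            "point_value")
        assert results["anti"].overall < results["own"].overall
        assert results["anti"].spearman_rho < 0

    def test_single_service_rejected(self):
        truth = gen_true_surface(WorldSpec(grid_rows=16, grid_cols=16, seed=1))
        vs = gen_validation(truth, "point", 10, obs_noise_sd=0.0, seed=3)
        with pytest.raises(ValueError):
            proxy_and_bundle_accuracy({"only": self._service(truth, 2)}, vs,
                                      "point_value")
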