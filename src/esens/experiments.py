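"""Canonical seeded simulation studies over synthetic worlds.

These functions define the package's reference study conditions — the world
sizes, model counts, distortion levels and couplings under which the
pipeline's statistical properties (portfolio effect, SEM-as-accuracy-proxy,
driver-test calibration and power) are demonstrated.  Both the test suite
and the reproduction script run them, so the numbers they report are always
recomputed from scratch.

World seeds are derived from one base seed through SeedSequence spawn keys,
so every study is reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .drivers import DriverDesign, driver_anova, driver_battery
from .ensemble import build_ensemble, renormalize_full_range, winsorise_raster
from .grids import ModelStack, Raster
from .pipeline import simulate_plot_accuracy
from .synthetic import (CountrySpec, ModelSpec, WorldSpec, _rng,
                        _smooth_standard_field, default_model_specs,
                        gen_model_outputs, gen_true_surface, gen_validation)
from .validation import (_normalize_vector, extract_predictions,
                         improvement_vs_random_model, score_predictor)

__all__ = [
    "portfolio_effect_study",
    "sem_accuracy_proxy_study",
    "driver_null_calibration_study",
    "driver_power_study",
]


def _world_seed(base_seed: int, study: int, i: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=(200 + study, i))
    return int(ss.generate_state(1)[0] % (2**31))


def _ensemble_improvement(seed: int, shared_bias: bool) -> float:
    """Ensemble-minus-median-model accuracy (percentage points) for one world.

    Idiosyncratic worlds: 9 models with individual smooth bias surfaces and
    independent noise (sd 0.15).  Shared-bias worlds: all idiosyncratic terms
    zeroed, one bias surface common to every model — the ensemble then has
    nothing to cancel.
    """
    world = WorldSpec(grid_rows=64, grid_cols=64, correlation_length=8, seed=seed)
    truth = gen_true_surface(world)
    if shared_bias:
        specs = [ModelSpec(f"m{i:02d}", shared_bias_weight=0.5) for i in range(9)]
    else:
        specs = default_model_specs(9, noise_sd=0.15, bias_field_weight=0.3,
                                    shared_bias_weight=0.0)
    stack = gen_model_outputs(truth, specs, seed=seed)
    norm = ModelStack({m: winsorise_raster(stack[m])[0] for m in stack.ids})
    ens = renormalize_full_range(build_ensemble(norm, "median"))
    vs = gen_validation(truth, "point", 150, obs_noise_sd=0.02, seed=seed)
    ens_acc = score_predictor(ens.values, vs, "point_value", label="ensemble")
    model_accs = [score_predictor(norm[m], vs, "point_value", label=m)
                  for m in stack.ids]
    return improvement_vs_random_model(ens_acc, model_accs)


def portfolio_effect_study(base_seed: int = 0, n_seeds: int = 200,
                           shared_bias: bool = False) -> np.ndarray:
    """Per-seed ensemble improvement (pp) over the median model."""
    return np.array([
        _ensemble_improvement(_world_seed(base_seed, 1 + int(shared_bias), i),
                              shared_bias)
        for i in range(n_seeds)
    ])


def sem_accuracy_proxy_study(base_seed: int = 0, n_seeds: int = 100
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and p between per-unit SEM and ensemble absolute error.

    Worlds have heterogeneous noise on two axes: per-model noise sd varies
    from 0.1 to 0.4, and a smooth "difficulty" field (amplitude 0.1 to 3.0)
    scales every model's noise locally — regions that are hard for all
    models.  400 point units per world.
    """
    rhos, ps = [], []
    for i in range(n_seeds):
        seed = _world_seed(base_seed, 3, i)
        world = WorldSpec(grid_rows=48, grid_cols=48, correlation_length=6, seed=seed)
        truth = gen_true_surface(world)
        f = _smooth_standard_field(_rng(seed, 9), truth.grid.shape, 6.0)
        f = (f - f.min()) / (f.max() - f.min())
        difficulty = Raster(0.1 + 2.9 * f, np.zeros(truth.grid.shape, bool), truth.grid)
        noises = np.linspace(0.1, 0.4, 7)
        specs = [ModelSpec(f"m{k}", noise_sd=float(noises[k])) for k in range(7)]
        stack = gen_model_outputs(truth, specs, seed=seed, noise_scale=difficulty)
        norm = ModelStack({m: winsorise_raster(stack[m])[0] for m in stack.ids})
        ens = renormalize_full_range(build_ensemble(norm, "median"))
        vs = gen_validation(truth, "point", 400, obs_noise_sd=0.0, seed=seed)
        Y = extract_predictions(ens.values, vs, "point_value").values
        S = extract_predictions(ens.sem, vs, "point_value").values
        X = _normalize_vector(vs.observed)
        Yn = _normalize_vector(Y)
        rho, p = stats.spearmanr(S, np.abs(X - Yn))
        rhos.append(rho)
        ps.append(p)
    return np.array(rhos), np.array(ps)


# study conditions for the driver calibration/power experiments
_DRIVER_WORLD = dict(grid_rows=32, grid_cols=32, correlation_length=6.0)
_DRIVER_N_COUNTRIES = 178
_DRIVER_NOISE_SD = 0.3
_DRIVER_K = 5
POWER_COUPLING = -0.9  # induces corr(metric, accuracy) of about 0.45 at n=178


def _driver_world(seed: int, coupling: float):
    world = WorldSpec(seed=seed, **_DRIVER_WORLD)
    specs = [ModelSpec(f"m{k}", noise_sd=_DRIVER_NOISE_SD) for k in range(_DRIVER_K)]
    cspec = CountrySpec(n_countries=_DRIVER_N_COUNTRIES, accuracy_coupling=coupling,
                        coupled_metric="hdi")
    return simulate_plot_accuracy(world, specs, cspec, seed=seed)


def driver_null_calibration_study(base_seed: int = 0, n_worlds: int = 500
                                  ) -> np.ndarray:
    """Whether the Hochberg-corrected battery rejects anything, per null world."""
    out = []
    for i in range(n_worlds):
        seed = _world_seed(base_seed, 4, i)
        D, countries, _ = _driver_world(seed, coupling=0.0)
        table = driver_battery(D, countries.centroids, countries.metrics)
        out.append(bool(table["significant"].any()))
    return np.array(out)


def driver_power_study(base_seed: int = 0, n_worlds: int = 200,
                       coupling: float = POWER_COUPLING
                       ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided detection of the coupled metric, and the realized correlation.

    Returns (detected, realized_corr) per world: whether the coupled metric's
    one-sided p (after the Auto covariate) falls below 0.05, and the plain
    correlation between the metric and per-country accuracy.
    """
    detected, corr = [], []
    for i in range(n_worlds):
        seed = _world_seed(base_seed, 5, i)
        D, countries, _ = _driver_world(seed, coupling=coupling)
        metric = countries.metrics["hdi"].to_numpy()
        design = DriverDesign(D, countries.centroids, metric)
        res = driver_anova(design)
        detected.append(res.factor("Metric").p_one < 0.05)
        corr.append(float(np.corrcoef(metric, D)[0, 1]))
    return np.array(detected), np.array(corr)
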