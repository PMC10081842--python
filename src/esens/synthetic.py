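"""Seeded synthetic worlds for testing the ensemble pipeline end to end.

Generates latent "true service" surfaces, distorted model outputs, validation
units (points / polygons / catchments) and country tilings with development
covariates.  Every generator is a pure function of its spec and seed, so any
downstream stage can be exercised against known ground truth without any
external data.

The statistical structure mirrors what the analysis assumes about real model
stacks: each model output is the truth under a multiplicative gain, plus a
smooth model-specific ("idiosyncratic") bias surface, plus a bias surface
shared by all models, plus noise, with partial spatial coverage.  Shared bias
is what limits the accuracy gain of an ensemble (no cancellation); the
idiosyncratic parts are what the committee median suppresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, ModelStack, Raster, ValidationSet, ValidationUnit

__all__ = [
    "WorldSpec",
    "ModelSpec",
    "CountrySpec",
    "gen_true_surface",
    "gen_model_outputs",
    "gen_validation",
    "gen_countries",
    "default_model_specs",
    "DEFAULT_METRIC_NAMES",
]

DEFAULT_METRIC_NAMES = ("gdp_pc", "hdi", "gini", "researchers_pm", "rd_gdp_pct")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, key...)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class WorldSpec:
    """Geometry and smoothness of a synthetic world.

    ``correlation_length`` is the Gaussian smoothing width (in cells) of the
    latent surface; 1 means no smoothing (i.i.d. cells).
    """

    grid_rows: int = 64
    grid_cols: int = 64
    cell_size: float = 0.1
    correlation_length: float = 8.0
    seed: int = 0
    origin_x: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8 cells a side")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1")

    @property
    def grid(self) -> GridSpec:
        # origin_y chosen so the southern edge sits at latitude 0
        return GridSpec(
            origin_x=self.origin_x,
            origin_y=self.grid_rows * self.cell_size,
            cell_size=self.cell_size,
            n_rows=self.grid_rows,
            n_cols=self.grid_cols,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Distortion recipe for one synthetic model output.

    value = bias_gain * truth + bias_field_weight * own_field
            + shared_bias_weight * shared_field + noise
    with ``coverage_fraction`` of cells retained (rest no-data).
    ``noise_correlation_length`` > 1 makes the noise spatially clustered.
    """

    model_id: str
    bias_gain: float = 1.0
    bias_field_weight: float = 0.0
    shared_bias_weight: float = 0.0
    noise_sd: float = 0.0
    coverage_fraction: float = 1.0
    noise_correlation_length: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CountrySpec:
    """Country tiling with development/equality covariates.

    ``accuracy_coupling`` links the named metric to local model noise through
    a per-cell multiplier exp(coupling * z(metric)); 0 gives a null world in
    which the metrics are independent of accuracy.
    """

    n_countries: int
    metric_names: Sequence[str] = DEFAULT_METRIC_NAMES
    accuracy_coupling: float = 0.0
    coupled_metric: str = "hdi"

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")


# ---------------------------------------------------------------------------
# Latent surface


def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                           corr_length: float) -> np.ndarray:
    """White noise, optionally Gaussian-smoothed, restandardized to sd 1."""
    z = rng.standard_normal(shape)
    if corr_length > 1:
        z = gaussian_filter(z, sigma=corr_length, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


def gen_true_surface(spec: WorldSpec) -> Raster:
    """Latent true-service surface in [0, 1], autocorrelated per the spec."""
    rng = _rng(spec.seed, 0)
    z = rng.standard_normal((spec.grid_rows, spec.grid_cols))
    if spec.correlation_length > 1:
        z = gaussian_filter(z, sigma=spec.correlation_length, mode="reflect")
    lo, hi = z.min(), z.max()
    if hi <= lo:  # pragma: no cover - white noise is never constant
        raise ValueError("degenerate (constant) surface")
    vals = (z - lo) / (hi - lo)
    return Raster(vals, np.zeros(spec.grid.shape, dtype=bool), spec.grid)


# ---------------------------------------------------------------------------
# Model outputs


def default_model_specs(k: int, noise_sd: float = 0.15, bias_field_weight: float = 0.3,
                        shared_bias_weight: float = 0.1, coverage_fraction: float = 1.0,
                        noise_correlation_length: float = 0.0) -> list[ModelSpec]:
    """K models with mildly varying gains and idiosyncratic bias surfaces."""
    gains = np.linspace(0.85, 1.15, k)
    return [
        ModelSpec(
            model_id=f"m{i:02d}",
            bias_gain=float(gains[i]),
            bias_field_weight=bias_field_weight,
            shared_bias_weight=shared_bias_weight,
            noise_sd=noise_sd,
            coverage_fraction=coverage_fraction,
            noise_correlation_length=noise_correlation_length,
        )
        for i in range(k)
    ]


def gen_model_outputs(truth: Raster, specs: Sequence[ModelSpec], seed: int,
                      noise_scale: Raster | None = None,
                      field_correlation_length: float = 8.0) -> ModelStack:
    """Distorted copies of the truth, one per ModelSpec.

    ``noise_scale`` (e.g. from :func:`gen_countries`) multiplies each model's
    noise standard deviation per cell, coupling accuracy to covariates.
    """
    ids = [s.model_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model_id in specs")
    shape = truth.grid.shape
    shared = _smooth_standard_field(_rng(seed, 1), shape, field_correlation_length)
    scale = noise_scale.values if noise_scale is not None else 1.0
    layers: dict[str, Raster] = {}
    for i, s in enumerate(specs):
        rng = _rng(seed, 2, i)
        vals = s.bias_gain * truth.values
        if s.bias_field_weight != 0.0:
            own = _smooth_standard_field(rng, shape, field_correlation_length)
            vals = vals + s.bias_field_weight * own
        if s.shared_bias_weight != 0.0:
            vals = vals + s.shared_bias_weight * shared
        if s.noise_sd > 0:
            if s.noise_correlation_length > 1:
                noise = _smooth_standard_field(rng, shape, s.noise_correlation_length)
            else:
                noise = rng.standard_normal(shape)
            vals = vals + s.noise_sd * scale * noise
        mask = truth.nodata_mask.copy()
        if s.coverage_fraction < 1.0:
            mask |= rng.random(shape) >= s.coverage_fraction
        layers[s.model_id] = Raster(np.where(mask, 0.0, vals), mask, truth.grid)
    return ModelStack(layers)


# ---------------------------------------------------------------------------
# Grid tiling (countries / polygon validation units)


def _tile_grid(grid: GridSpec, k: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid cells into k contiguous regions; returns labels.

    k-means on cell-centre coordinates gives irregular but convex (hence
    contiguous) Voronoi-like regions; a deterministic Voronoi fallback covers
    the rare empty-cluster outcome.
    """
    if k > grid.n_cells:
        raise ValueError("more regions than grid cells")
    xx, yy = grid.center_grids()
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    for attempt in range(5):
        seed = int(rng.integers(2**31))
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, labels = kmeans2(coords, k, minit="++", seed=seed)
        except Exception:  # pragma: no cover - kmeans2 init failure
            continue
        if len(np.unique(labels)) == k:
            return labels.reshape(grid.shape)
    # Voronoi fallback: k random distinct cells as centres
    centers = coords[rng.choice(grid.n_cells, size=k, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(grid.shape)


def _aggregate_labels(values: np.ndarray, mask: np.ndarray, labels: np.ndarray,
                      k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-label sum over data cells and data-cell counts."""
    valid = ~mask.ravel()
    lab = labels.ravel()[valid]
    sums = np.bincount(lab, weights=values.ravel()[valid], minlength=k)
    counts = np.bincount(lab, minlength=k)
    return sums, counts


# ---------------------------------------------------------------------------
# Validation sets


def gen_validation(truth: Raster, unit_kind: str, n_units: int, obs_noise_sd: float,
                   seed: int) -> ValidationSet:
    """Validation units whose observations are truth aggregates plus noise.

    point: the containing cell's value; polygon/catchment: the sum over the
    unit's cells.  Catchments additionally carry a pour-point cell (the
    maximum-truth cell of the unit, the synthetic stand-in for the flow
    outlet that max-aggregation targets).
    """
    if unit_kind not in ("point", "polygon", "catchment"):
        raise ValueError(f"unknown unit_kind {unit_kind!r}")
    if n_units < 2:
        raise ValueError("need at least 2 validation units")
    grid = truth.grid
    rng = _rng(seed, 3)
    units: list[ValidationUnit] = []
    label_map = np.full(grid.shape, -1, dtype=int)

    if unit_kind == "point":
        data_flat = np.flatnonzero(~truth.nodata_mask.ravel())
        if n_units > data_flat.size:
            raise ValueError("more point units than available data cells")
        chosen = rng.choice(data_flat, size=n_units, replace=False)
        noise = rng.standard_normal(n_units) * obs_noise_sd
        for i, flat in enumerate(chosen):
            r, c = np.unravel_index(flat, grid.shape)
            x, y = grid.cell_center(r, c)
            units.append(ValidationUnit(
                unit_id=f"p{i:04d}", kind="point",
                observed=float(truth.values[r, c] + noise[i]),
                centroid=(x, y), cells=np.array([flat]),
            ))
            label_map[r, c] = i
    else:
        labels = _tile_grid(grid, n_units, rng)
        label_map = labels.copy()
        sums, _ = _aggregate_labels(truth.values, truth.nodata_mask, labels.ravel(), n_units)
        noise = rng.standard_normal(n_units) * obs_noise_sd
        xx, yy = grid.center_grids()
        for i in range(n_units):
            cells = np.flatnonzero(labels.ravel() == i)
            cx = float(xx.ravel()[cells].mean())
            cy = float(yy.ravel()[cells].mean())
            pour = None
            if unit_kind == "catchment":
                vals = np.where(truth.nodata_mask.ravel()[cells], -np.inf,
                                truth.values.ravel()[cells])
                pr, pc = np.unravel_index(cells[int(np.argmax(vals))], grid.shape)
                pour = (int(pr), int(pc))
            units.append(ValidationUnit(
                unit_id=f"u{i:04d}", kind=unit_kind,
                observed=float(sums[i] + noise[i]),
                centroid=(cx, cy), cells=cells, pour_point=pour,
            ))
    return ValidationSet(kind=unit_kind, grid=grid, units=units, label_map=label_map,
                         meta={"seed": seed, "obs_noise_sd": obs_noise_sd})


# ---------------------------------------------------------------------------
# Countries with development metrics


def _draw_metrics(rng: np.random.Generator, names: Sequence[str], k: int) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name == "gdp_pc":
            cols[name] = np.exp(rng.normal(9.5, 1.0, size=k))  # USD per capita
        elif name == "hdi":
            cols[name] = np.clip(rng.normal(0.70, 0.15, size=k), 0.35, 0.97)
        elif name == "gini":
            cols[name] = rng.uniform(25.0, 60.0, size=k)
        elif name == "researchers_pm":
            cols[name] = np.exp(rng.normal(6.5, 1.2, size=k))  # per million
        elif name == "rd_gdp_pct":
            cols[name] = rng.uniform(0.1, 3.5, size=k)
        else:
            cols[name] = rng.normal(0.0, 1.0, size=k)
    idx = pd.Index([f"c{i:04d}" for i in range(k)], name="country_id")
    return pd.DataFrame(cols, index=idx)


def gen_countries(spec: CountrySpec, world: WorldSpec, seed: int,
                  truth: Raster | None = None, obs_noise_sd: float = 0.0) -> ValidationSet:
    """Contiguous country polygons with metrics and optional accuracy coupling.

    Observations are truth sums per country plus Gaussian noise (so the set
    doubles as a polygon validation set).  With ``accuracy_coupling`` != 0 the
    returned set carries a per-cell ``noise_scale`` raster,
    exp(coupling * z(metric)), to be passed to :func:`gen_model_outputs`.
    """
    grid = world.grid
    if spec.n_countries > grid.n_cells:
        raise ValueError("more countries than grid cells")
    if truth is None:
        truth = gen_true_surface(world)
    rng = _rng(seed, 4)
    labels = _tile_grid(grid, spec.n_countries, rng)
    metrics = _draw_metrics(rng, spec.metric_names, spec.n_countries)

    sums, _ = _aggregate_labels(truth.values, truth.nodata_mask, labels.ravel(),
                                spec.n_countries)
    noise = rng.standard_normal(spec.n_countries) * obs_noise_sd
    xx, yy = grid.center_grids()
    units = []
    for i in range(spec.n_countries):
        cells = np.flatnonzero(labels.ravel() == i)
        units.append(ValidationUnit(
            unit_id=f"c{i:04d}", kind="polygon",
            observed=float(sums[i] + noise[i]),
            centroid=(float(xx.ravel()[cells].mean()), float(yy.ravel()[cells].mean())),
            cells=cells,
        ))

    noise_scale = None
    if spec.accuracy_coupling != 0.0:
        if spec.coupled_metric not in metrics.columns:
            raise ValueError(f"coupled metric {spec.coupled_metric!r} not generated")
        v = metrics[spec.coupled_metric].to_numpy()
        z = (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)
        mult = np.clip(1.0 + spec.accuracy_coupling * z, 0.05, None)
        noise_scale = Raster(mult[labels], np.zeros(grid.shape, dtype=bool), grid)

    return ValidationSet(
        kind="polygon", grid=grid, units=units, label_map=labels,
        metrics=metrics, noise_scale=noise_scale,
        meta={"seed": seed, "accuracy_coupling": spec.accuracy_coupling,
              "coupled_metric": spec.coupled_metric, "obs_noise_sd": obs_noise_sd},
    )
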