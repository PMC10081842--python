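"""Normalization and unweighted per-cell ensembles with uncertainty layers.

Normalization is double-sided Winsorising: the 2.5th and 97.5th percentiles
of a layer's data cells define 0 and 1, values beyond them are clamped, and
everything in between is rescaled linearly.  This limits the influence of
extreme values without dropping them and puts model outputs in arbitrary
native units onto one comparable [0, 1] scale (the same protocol is applied
to validation vectors before scoring).

The ensemble is the per-cell median (or mean) over the contributing models;
per-cell spread is reported as the standard error of the mean,
SEM(x) = sigma(x) / sqrt(n(x)), with sigma the sample standard deviation
(n - 1 denominator) and n(x) the number of models with data at x.  SEM is
undefined (no-data) where fewer than two models contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .grids import ModelStack, Raster, ValidationSet, polygon_cell_indices

__all__ = [
    "NormalizationParams",
    "EnsembleLayer",
    "winsorise_fit",
    "winsorise_apply",
    "winsorise_raster",
    "build_ensemble",
    "renormalize_full_range",
    "catchment_aggregate",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted Winsorising cut values for one layer or vector."""

    lower_pct: float
    upper_pct: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower_pct < self.upper_pct:
            raise ValueError("lower_pct must be below upper_pct")
        if not self.lower <= self.upper:
            raise ValueError("fitted lower cut exceeds upper cut")


def winsorise_fit(values: np.ndarray, lower_pct: float = 2.5,
                  upper_pct: float = 97.5) -> NormalizationParams:
    """Fit the percentile cut values on the finite entries of ``values``.

    Percentiles use linear interpolation between order statistics.  Raises on
    degenerate input (fewer than two distinct finite values, or coincident
    cuts).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct finite values to fit")
    lower, upper = np.percentile(v, [lower_pct, upper_pct])
    if upper <= lower:
        raise ValueError("degenerate input: percentile cuts coincide")
    return NormalizationParams(lower_pct, upper_pct, float(lower), float(upper))


def winsorise_apply(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map v -> clip((v - lower)/(upper - lower), 0, 1); NaN passes through."""
    if params.upper <= params.lower:
        raise ValueError("cannot apply degenerate cuts (upper == lower)")
    v = np.asarray(values, dtype=float)
    out = (v - params.lower) / (params.upper - params.lower)
    return np.clip(out, 0.0, 1.0, out=out)


def winsorise_raster(r: Raster, params: NormalizationParams | None = None,
                     lower_pct: float = 2.5, upper_pct: float = 97.5,
                     ) -> tuple[Raster, NormalizationParams]:
    """Winsorise a raster layer; cuts are fitted on its data cells only."""
    if params is None:
        params = winsorise_fit(r.data_values, lower_pct, upper_pct)
    vals = winsorise_apply(r.values, params)
    return r.with_values(np.where(r.nodata_mask, 0.0, vals)), params


@dataclass
class EnsembleLayer:
    """Per-cell ensemble values with SEM and model-count layers."""

    statistic: str
    values: Raster
    sem: Raster
    n_models: Raster

    @property
    def grid(self):
        return self.values.grid


def build_ensemble(stack: ModelStack, statistic: str = "median",
                   weights: Sequence[float] | None = None) -> EnsembleLayer:
    """Per-cell committee statistic over the normalized model layers.

    ``statistic`` is "median" or "mean"; a per-model ``weights`` vector turns
    "mean" into a weighted cell mean (the plug-in point for externally
    derived weighting schemes).  True zeros count; no-data cells are ignored;
    cells where no model has data are no-data.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    arr = stack.as_array()  # (K, R, C) with NaN at no-data
    n = stack.count()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if statistic == "median":
            if weights is not None:
                raise ValueError("weights apply to the mean statistic only")
            vals = np.nanmedian(arr, axis=0)
        elif statistic == "mean":
            if weights is None:
                vals = np.nanmean(arr, axis=0)
            else:
                w = np.asarray(weights, dtype=float)
                if w.shape != (len(stack),) or np.any(w < 0) or w.sum() <= 0:
                    raise ValueError("weights must be non-negative, one per model")
                denom = (w[:, None, None] * ~np.isnan(arr)).sum(axis=0)
                num = np.nansum(w[:, None, None] * arr, axis=0)
                vals = np.divide(num, denom, out=np.full(denom.shape, np.nan),
                                 where=denom > 0)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        sd = np.nanstd(arr, axis=0, ddof=1)
    value_mask = ~np.isfinite(vals)  # n == 0, or zero total weight
    sem_mask = n < 2
    sem = np.where(sem_mask, 0.0, sd / np.sqrt(np.maximum(n, 1)))
    grid = stack.grid
    return EnsembleLayer(
        statistic=statistic,
        values=Raster(np.where(value_mask, 0.0, vals), value_mask, grid),
        sem=Raster(sem, sem_mask, grid),
        n_models=Raster(n.astype(float), np.zeros(grid.shape, dtype=bool), grid),
    )


def minmax_rescale(r: Raster) -> Raster:
    """Affine map of the data cells onto exactly [0, 1]."""
    data = r.data_values
    if data.size == 0:
        raise ValueError("no data cells to rescale")
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("constant layer cannot be rescaled to a full range")
    vals = (r.values - lo) / (hi - lo)
    return r.with_values(np.where(r.nodata_mask, 0.0, vals))


def renormalize_full_range(layer: EnsembleLayer) -> EnsembleLayer:
    """Rescale the ensemble values so they span the full 0-1 range.

    Only the value layer is rescaled; SEM and counts keep their scales.
    """
    return EnsembleLayer(
        statistic=layer.statistic,
        values=minmax_rescale(layer.values),
        sem=layer.sem,
        n_models=layer.n_models,
    )


def catchment_aggregate(r: Raster, polygons, mode: str = "sum") -> np.ndarray:
    """Per-polygon sum or max of the data cells; NaN marks empty polygons.

    ``polygons`` is a :class:`ValidationSet` (label fast path when its units
    were defined as cell sets on the raster's grid) or a sequence of shapely
    geometries.  No-data cells are ignored; a polygon with zero data cells is
    flagged missing (NaN).
    """
    if mode not in ("sum", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(polygons, ValidationSet):
        vs = polygons
        if vs.label_map is not None and vs.grid.approx_equal(r.grid):
            cell_sets = [np.asarray(u.cells) for u in vs.units]
        else:
            cell_sets = [polygon_cell_indices(r.grid, vs.geometry(i))
                         for i in range(len(vs))]
    else:
        cell_sets = [polygon_cell_indices(r.grid, g) for g in polygons]
    flat_vals = r.values.ravel()
    flat_mask = r.nodata_mask.ravel()
    out = np.full(len(cell_sets), np.nan)
    for i, cells in enumerate(cell_sets):
        if cells.size == 0:
            continue
        vals = flat_vals[cells][~flat_mask[cells]]
        if vals.size == 0:
            continue
        out[i] = vals.sum() if mode == "sum" else vals.max()
    return out
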