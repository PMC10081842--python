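"""Score predictors against validation data and compare them by bootstrap.

The accuracy statistic is the inverse of deviance,

    D = 1 - (1/n) * sum_x |X(x) - Y(x)|,

with X the normalized observation and Y the normalized prediction at unit x
(per-point accuracy is 1 - |X - Y|).  Both vectors are brought onto [0, 1]
by the same double-sided Winsorising protocol that normalizes the model
layers, so D is a unit-free skill score: 1 is perfect agreement, 0 maximal
disagreement.  Spearman rank correlation is carried alongside as an
alternative accuracy measure.

Model-versus-ensemble comparisons resample validation units (subsampling
without replacement by default), score *every* predictor on the identical
resample, and test per-run accuracy differences with paired t tests under a
Hochberg step-up correction for multiplicity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleLayer, minmax_rescale, winsorise_apply, winsorise_fit
from .grids import ModelStack, Raster, ValidationSet, cells_within_radius

__all__ = [
    "PredictionVector",
    "AccuracyResult",
    "ComparisonResult",
    "extract_predictions",
    "deviance_accuracy",
    "score_predictor",
    "bootstrap_compare",
    "hochberg_correct",
    "improvement_vs_random_model",
    "proxy_and_bundle_accuracy",
]


@dataclass
class PredictionVector:
    """Per-unit predicted values aligned 1:1 with a ValidationSet."""

    label: str
    values: np.ndarray  # NaN = missing (no data cells at the unit)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(~np.isfinite(self.values)))


@dataclass
class AccuracyResult:
    """Inverse-of-deviance accuracy of one predictor on one validation set."""

    label: str
    per_point: np.ndarray
    overall: float
    spearman_rho: float
    spearman_p: float
    n: int


@dataclass
class ComparisonResult:
    """Bootstrap accuracies per predictor with pairwise paired t tests."""

    labels: list[str]
    run_accuracies: np.ndarray  # (n_runs, n_predictors)
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    pairs: pd.DataFrame  # a, b, mean_diff, t, p, significant
    n_runs: int
    sample_size: int
    dropped_units: int = 0


# ---------------------------------------------------------------------------
# Extraction


def extract_predictions(r: Raster, vs: ValidationSet, mode: str,
                        radius: float | None = None) -> PredictionVector:
    """Predicted value per validation unit from a raster.

    Modes: ``polygon_sum`` (sum of the unit's data cells), ``point_value``
    (value of the containing cell) and ``max_within_radius`` (maximum data
    value within ``radius`` degrees of the unit's reference location, without
    leaving the unit's own cells when it has any — the flow-routing
    correction for accumulated-flow layers at gauging stations).  Units
    without data cells are missing (NaN).
    """
    if mode not in ("polygon_sum", "point_value", "max_within_radius"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "max_within_radius" and radius is None:
        raise ValueError("max_within_radius requires a radius")
    grid = r.grid
    flat_vals = r.values.ravel()
    flat_mask = r.nodata_mask.ravel()
    out = np.full(len(vs), np.nan)
    for i, u in enumerate(vs.units):
        if mode == "polygon_sum":
            cells = (np.asarray(u.cells) if u.cells is not None and vs.grid.approx_equal(grid)
                     else None)
            if cells is None:
                from .grids import polygon_cell_indices

                cells = polygon_cell_indices(grid, vs.geometry(i))
        elif mode == "point_value":
            row, col = grid.cell_of(*u.centroid)
            cells = np.array([row * grid.n_cols + col])
        else:  # max_within_radius
            if u.pour_point is not None:
                px, py = grid.cell_center(*u.pour_point)
            else:
                px, py = u.centroid
            if radius <= 0:
                row, col = grid.cell_of(px, py)
                cells = np.array([row * grid.n_cols + col])
            else:
                cells = cells_within_radius(grid, px, py, radius)
                # stay inside the unit's own watershed, if it has an area
                if (u.kind in ("polygon", "catchment") and u.cells is not None
                        and vs.grid.approx_equal(grid)):
                    cells = np.intersect1d(cells, np.asarray(u.cells))
        if cells.size == 0:
            continue
        vals = flat_vals[cells][~flat_mask[cells]]
        if vals.size == 0:
            continue
        if mode == "polygon_sum":
            out[i] = vals.sum()
        elif mode == "point_value":
            out[i] = vals[0]
        else:
            out[i] = vals.max()
    return PredictionVector(label="raster", values=out)


# ---------------------------------------------------------------------------
# Accuracy


def deviance_accuracy(X: np.ndarray, Y: PredictionVector | np.ndarray) -> AccuracyResult:
    """Inverse-of-deviance accuracy of normalized predictions Y against X."""
    label = Y.label if isinstance(Y, PredictionVector) else "predictor"
    y = Y.values if isinstance(Y, PredictionVector) else np.asarray(Y, dtype=float)
    x = np.asarray(X, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if x.size < 2:
        raise ValueError("need at least 2 units")
    if np.any((x < 0) | (x > 1)) or np.any((y < 0) | (y > 1)):
        raise ValueError("inputs must be normalized to [0, 1]")
    per_point = 1.0 - np.abs(x - y)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=stats.ConstantInputWarning)
        rho, p = stats.spearmanr(x, y)
    return AccuracyResult(
        label=label,
        per_point=per_point,
        overall=float(per_point.mean()),
        spearman_rho=float(rho),
        spearman_p=float(p),
        n=x.size,
    )


def _normalize_vector(v: np.ndarray) -> np.ndarray:
    """Winsorise a raw vector onto [0, 1] (own 2.5/97.5 percentile cuts)."""
    return winsorise_apply(v, winsorise_fit(v))


def score_predictor(r: Raster, vs: ValidationSet, mode: str,
                    radius: float | None = None, label: str = "predictor",
                    normalize: bool = True) -> AccuracyResult:
    """Extract, Winsorise (both sides) and score one raster predictor.

    Units with missing predictions are dropped before normalization; their
    count is recorded on the result via ``n`` versus ``len(vs)``.
    """
    pred = extract_predictions(r, vs, mode, radius)
    keep = np.isfinite(pred.values)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 units with data")
    x, y = vs.observed[keep], pred.values[keep]
    if normalize:
        x, y = _normalize_vector(x), _normalize_vector(y)
    res = deviance_accuracy(x, PredictionVector(label=label, values=y))
    return res


# ---------------------------------------------------------------------------
# Multiple testing


def hochberg_correct(p: np.ndarray, alpha: float = 0.05,
                     m: int | None = None) -> np.ndarray:
    """Hochberg step-up significance flags, returned in input order.

    Sorts the p values ascending and rejects hypotheses 1..k for the largest
    k with p_(k) <= alpha / (m - k + 1); ``m`` (>= len(p)) is the size of the
    test family, which may exceed the number of p values supplied.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("family size m must be >= len(p)")
    order = np.argsort(p, kind="stable")
    k_reject = 0
    for k in range(n, 0, -1):
        if p[order[k - 1]] <= alpha / (m - k + 1):
            k_reject = k
            break
    flags = np.zeros(n, dtype=bool)
    flags[order[:k_reject]] = True
    return flags


# ---------------------------------------------------------------------------
# Bootstrap comparison


def bootstrap_compare(predictors: list[PredictionVector], X: np.ndarray,
                      n_runs: int = 1000, sample_rule: tuple[str, float] = ("fraction", 0.10),
                      replace: bool = False, alpha: float = 0.05,
                      m_tests: int | None = None, seed: int = 0,
                      normalize: bool = True) -> ComparisonResult:
    """Resample units, score every predictor on the identical resample.

    ``sample_rule`` is ("fraction", f) or ("fixed", k) units per run.
    Accuracies are compared pairwise with paired t tests across runs and the
    p values are Hochberg-corrected (family size ``m_tests``, default the
    number of pairs).  Units missing in any predictor are dropped listwise so
    all predictors are scored on identical units.
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = np.asarray(X, dtype=float)
    ys = np.stack([p.values for p in predictors])  # (P, n)
    keep = np.isfinite(X) & np.all(np.isfinite(ys), axis=0)
    dropped = int(np.count_nonzero(~keep))
    X, ys = X[keep], ys[:, keep]
    n = X.size
    rule, value = sample_rule
    if rule == "fraction":
        size = max(2, int(round(value * n)))
    elif rule == "fixed":
        size = min(int(value), n)
    else:
        raise ValueError(f"unknown sample rule {rule!r}")
    if size < 2:
        raise ValueError("resample size must be >= 2")

    if normalize:
        Xn = _normalize_vector(X)
        Yn = np.stack([_normalize_vector(y) for y in ys])
    else:
        Xn, Yn = X, ys

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    acc = np.empty((n_runs, len(predictors)))
    for run in range(n_runs):
        idx = rng.choice(n, size=size, replace=replace)
        acc[run] = 1.0 - np.abs(Xn[idx][None, :] - Yn[:, idx]).mean(axis=1)

    labels = [p.label for p in predictors]
    rows = []
    for i, j in itertools.combinations(range(len(predictors)), 2):
        diff = acc[:, i] - acc[:, j]
        if np.allclose(diff, 0.0):
            t, p_two = 0.0, 1.0
        else:
            t, p_two = stats.ttest_rel(acc[:, i], acc[:, j])
        rows.append({"a": labels[i], "b": labels[j], "mean_diff": float(diff.mean()),
                     "t": float(t), "p": float(p_two)})
    pairs = pd.DataFrame(rows)
    m = max(m_tests or len(pairs), len(pairs))
    pairs["significant"] = hochberg_correct(pairs["p"].to_numpy(), alpha=alpha, m=m)
    return ComparisonResult(
        labels=labels,
        run_accuracies=acc,
        mean_accuracy=acc.mean(axis=0),
        sd_accuracy=acc.std(axis=0, ddof=1),
        pairs=pairs,
        n_runs=n_runs,
        sample_size=size,
        dropped_units=dropped,
    )


def improvement_vs_random_model(ens: AccuracyResult,
                                models: list[AccuracyResult]) -> float:
    """Ensemble accuracy gain over a randomly picked model, in points.

    The baseline for "a random pick among models" is the median of the
    models' overall accuracies; the result is expressed in percentage points
    of inverse deviance per validation datapoint (negative if the ensemble
    is worse).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    baseline = float(np.median([m.overall for m in models]))
    return 100.0 * (ens.overall - baseline)


# ---------------------------------------------------------------------------
# Cross-service proxies and bundles


def proxy_and_bundle_accuracy(ensembles: dict[str, EnsembleLayer],
                              target_vs: ValidationSet, target_mode: str,
                              radius: float | None = None) -> dict[str, AccuracyResult]:
    """Score other-service ensembles (and their bundle) on a target's units.

    The bundle is the per-cell mean of the member ensembles' normalized
    values (no-data ignored), rescaled to the full 0-1 range, then extracted
    and scored exactly like any single predictor.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least 2 services for a bundle")
    results: dict[str, AccuracyResult] = {}
    for service, layer in ensembles.items():
        results[service] = score_predictor(layer.values, target_vs, target_mode,
                                           radius=radius, label=service)
    stack = ModelStack({s: e.values for s, e in ensembles.items()})
    arr = stack.as_array()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_vals = np.nanmean(arr, axis=0)
    mask = ~np.isfinite(mean_vals)
    bundle = Raster(np.where(mask, 0.0, mean_vals), mask, stack.grid)
    bundle = minmax_rescale(bundle)
    results["bundle"] = score_predictor(bundle, target_vs, target_mode,
                                        radius=radius, label="bundle")
    return results
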