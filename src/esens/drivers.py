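"""Test spatial drivers of per-point ensemble accuracy.

Fits the linear model

    D(x) ~ b0 + b1 * Auto(x) + b2 * Metric(x) + e

with sequential (type-I) sums of squares, Auto entered first, where D(x) is
the per-unit inverse of deviance, Metric(x) a (transformed) country-level
development/equality covariate, and Auto(x) a spatial-autocorrelation
covariate: the inverse-distance-weighted mean of D at all *other* points
within a maximum effect range (default 5 degrees, Euclidean in degrees).
Entering Auto first absorbs spatial dependence before the covariate of
interest is tested.

The directional hypothesis — accuracy increases with the metric — is tested
one-sided: p_one = p_two / 2 when the slope is positive, 1 - p_two / 2
otherwise, and reported F values carry the slope's sign ("mirrored").

A two-factor interaction model adds income equality and its product with
GDP: type-I between Auto and the factors, type-III (partial SS) among the
factors and interaction.

To standardize degrees of freedom across services, tests can be run through
a convergence bootstrap: repeatedly subsample a standard number of points
(default 178), accumulate the running mean of each factor's SS, and stop
once every factor's running mean changes by no more than 0.05% for 25
consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .validation import hochberg_correct

__all__ = [
    "DriverDesign",
    "FactorTest",
    "DriverTestResult",
    "auto_covariate",
    "transform_metric",
    "driver_anova",
    "interaction_model",
    "convergence_bootstrap",
    "driver_battery",
    "DEFAULT_METRIC_TRANSFORMS",
]

# transform kind and optional fixed scale divisor per canonical metric
DEFAULT_METRIC_TRANSFORMS: dict[str, tuple[str, float | None]] = {
    "gdp_pc": ("log10", None),
    "hdi": ("none", None),
    "gini": ("arcsine", 100.0),
    "researchers_pm": ("arcsine", 1e6),
    "rd_gdp_pct": ("arcsine", 100.0),
}


def auto_covariate(centroids: np.ndarray, D_per_point: np.ndarray,
                   max_range: float = 5.0) -> np.ndarray:
    """Inverse-distance-weighted neighbour mean of D within ``max_range``.

    Self-excluded.  Coincident neighbours (distance 0) dominate with equal
    weight; points with no neighbour in range fall back to the global mean.
    """
    pts = np.asarray(centroids, dtype=float)
    D = np.asarray(D_per_point, dtype=float)
    n = D.size
    if n < 2:
        raise ValueError("need at least 2 points")
    d = cdist(pts, pts)
    neigh = (d <= max_range) & ~np.eye(n, dtype=bool)
    auto = np.full(n, D.mean())
    for i in range(n):
        idx = np.flatnonzero(neigh[i])
        if idx.size == 0:
            continue
        di = d[i, idx]
        zeros = di == 0
        if zeros.any():
            auto[i] = D[idx[zeros]].mean()
        else:
            w = 1.0 / di
            auto[i] = float(np.dot(w, D[idx]) / w.sum())
    return auto


def transform_metric(values: np.ndarray, kind: str,
                     scale: float | None = None) -> np.ndarray:
    """Normality transform: arcsine(sqrt(v)), log10(v), or identity.

    For the arcsine, proportion-like metrics reported on a 0-100 (or other)
    scale are divided by ``scale`` first; if no scale is given and values
    exceed 1, a division by 100 is assumed.
    """
    v = np.asarray(values, dtype=float)
    if kind == "none":
        return v.copy()
    if kind == "log10":
        if np.any(v <= 0):
            raise ValueError("log10 transform needs strictly positive values")
        return np.log10(v)
    if kind == "arcsine":
        if scale is None:
            scale = 100.0 if np.nanmax(v) > 1.0 else 1.0
        v = v / scale
        if np.any((v < 0) | (v > 1)):
            raise ValueError("arcsine transform needs values scalable into [0, 1]")
        return np.arcsin(np.sqrt(v))
    raise ValueError(f"unknown transform {kind!r}")


@dataclass
class DriverDesign:
    """Per-point accuracy with its spatial covariate and tested metric."""

    D_per_point: np.ndarray
    centroids: np.ndarray
    metric: np.ndarray
    auto: np.ndarray = field(default=None)  # type: ignore[assignment]
    transform: str = "none"
    max_range: float = 5.0

    def __post_init__(self) -> None:
        self.D_per_point = np.asarray(self.D_per_point, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.metric = transform_metric(self.metric, self.transform)
        if self.auto is None:
            self.auto = auto_covariate(self.centroids, self.D_per_point, self.max_range)
        else:
            self.auto = np.asarray(self.auto, dtype=float)
        n = self.D_per_point.size
        if not (self.centroids.shape[0] == n == self.metric.size == self.auto.size):
            raise ValueError("design vectors differ in length")


@dataclass
class FactorTest:
    name: str
    ss: float
    df: int
    F: float
    F_signed: float
    p_two: float
    p_one: float
    coef: float


@dataclass
class DriverTestResult:
    factors: list[FactorTest]
    rss: float
    df_resid: int
    n: int
    converged: bool = True
    n_iterations: int | None = None

    def factor(self, name: str) -> FactorTest:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


def _rss(y: np.ndarray, cols: list[np.ndarray]) -> tuple[float, np.ndarray]:
    """Residual sum of squares and coefficients of OLS of y on [1, cols...]."""
    X = np.column_stack([np.ones_like(y)] + cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design")
    resid = y - X @ beta
    return float(resid @ resid), beta


def _factor(name: str, ss: float, ms_resid: float, df_resid: int,
            coef: float) -> FactorTest:
    F = ss / ms_resid if ms_resid > 0 else np.inf
    p_two = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
    p_one = p_two / 2.0 if coef > 0 else 1.0 - p_two / 2.0
    return FactorTest(name=name, ss=float(ss), df=1, F=float(F),
                      F_signed=float(np.sign(coef) * F) if np.isfinite(F) else np.inf,
                      p_two=p_two, p_one=p_one, coef=float(coef))


def driver_anova(design: DriverDesign) -> DriverTestResult:
    """Sequential-SS fit of D ~ Auto + Metric, Auto entered first."""
    y, auto, metric = design.D_per_point, design.auto, design.metric
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 points")
    for name, v in (("Auto", auto), ("Metric", metric)):
        if np.std(v) == 0:
            raise ValueError(f"constant covariate {name}")
    rss0, _ = _rss(y, [])
    rss1, _ = _rss(y, [auto])
    rss2, beta = _rss(y, [auto, metric])
    df_resid = n - 3
    ms_resid = rss2 / df_resid
    return DriverTestResult(
        factors=[
            _factor("Auto", rss0 - rss1, ms_resid, df_resid, beta[1]),
            _factor("Metric", rss1 - rss2, ms_resid, df_resid, beta[2]),
        ],
        rss=rss2, df_resid=df_resid, n=n,
    )


def interaction_model(D_per_point: np.ndarray, centroids: np.ndarray,
                      gdp: np.ndarray, equality: np.ndarray,
                      auto: np.ndarray | None = None,
                      gdp_transform: str = "log10",
                      equality_transform: str = "arcsine",
                      max_range: float = 5.0) -> DriverTestResult:
    """Two-factor interaction model for GDP and income equality.

    Type-I SS between the spatial covariate and the factors (Auto first),
    type-III (partial) SS among GDP, equality and their product.
    """
    y = np.asarray(D_per_point, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if auto is None:
        auto = auto_covariate(centroids, y, max_range)
    g = transform_metric(gdp, gdp_transform)
    e = transform_metric(equality, equality_transform)
    ge = g * e
    rss0, _ = _rss(y, [])
    rss_auto, _ = _rss(y, [auto])
    rss_full, beta = _rss(y, [auto, g, e, ge])
    df_resid = n - 5
    ms_resid = rss_full / df_resid
    rss_no_g, _ = _rss(y, [auto, e, ge])
    rss_no_e, _ = _rss(y, [auto, g, ge])
    rss_no_ge, _ = _rss(y, [auto, g, e])
    return DriverTestResult(
        factors=[
            _factor("Auto", rss0 - rss_auto, ms_resid, df_resid, beta[1]),
            _factor("GDP", rss_no_g - rss_full, ms_resid, df_resid, beta[2]),
            _factor("Equality", rss_no_e - rss_full, ms_resid, df_resid, beta[3]),
            _factor("GDPxEquality", rss_no_ge - rss_full, ms_resid, df_resid, beta[4]),
        ],
        rss=rss_full, df_resid=df_resid, n=n,
    )


def convergence_bootstrap(fit, y: np.ndarray, n_sample: int = 178,
                          tol: float = 5e-4, patience: int = 25,
                          max_iter: int = 2000, seed: int = 0,
                          n_params: int | None = None) -> DriverTestResult:
    """Stabilize a driver fit by subsampling to a standard sample size.

    ``fit(idx)`` must return a :class:`DriverTestResult` for the subsample
    ``idx`` (without replacement, size ``n_sample``).  The running mean of
    each factor's SS (and of the residual SS and coefficients) is
    accumulated; iteration stops once every factor's running-mean SS has
    changed by at most ``tol`` (relative) for ``patience`` consecutive
    iterations.  F values are recomputed from the converged mean SS with
    degrees of freedom standardized at ``n_sample``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < n_sample:
        raise ValueError("need at least n_sample points")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))

    sum_ss = None
    sum_rss = 0.0
    sum_coef = None
    names: list[str] = []
    streak = 0
    it = 0
    converged = False
    while it < max_iter:
        idx = rng.choice(n, size=n_sample, replace=False) if n > n_sample \
            else np.arange(n)
        res = fit(idx)
        ss = np.array([f.ss for f in res.factors])
        coef = np.array([f.coef for f in res.factors])
        if sum_ss is None:
            names = [f.name for f in res.factors]
            sum_ss = np.zeros_like(ss)
            sum_coef = np.zeros_like(coef)
            prev_mean = None
        else:
            prev_mean = sum_ss / it
        sum_ss += ss
        sum_rss += res.rss
        sum_coef += coef
        it += 1
        mean_ss = sum_ss / it
        if prev_mean is not None:
            denom = np.where(np.abs(prev_mean) > 0, np.abs(prev_mean), 1.0)
            if np.all(np.abs(mean_ss - prev_mean) / denom <= tol):
                streak += 1
            else:
                streak = 0
            if streak >= patience:
                converged = True
                break

    mean_ss = sum_ss / it
    mean_rss = sum_rss / it
    mean_coef = sum_coef / it
    p = (n_params if n_params is not None else len(names) + 1)
    df_resid = n_sample - p
    ms_resid = mean_rss / df_resid
    factors = [_factor(name, mean_ss[i], ms_resid, df_resid, mean_coef[i])
               for i, name in enumerate(names)]
    return DriverTestResult(factors=factors, rss=mean_rss, df_resid=df_resid,
                            n=n_sample, converged=converged, n_iterations=it)


def driver_battery(D_per_point: np.ndarray, centroids: np.ndarray,
                   metrics: pd.DataFrame,
                   transforms: dict[str, tuple[str, float | None]] | None = None,
                   alpha: float = 0.05, m_tests: int = 8,
                   gdp_col: str = "gdp_pc", equality_col: str = "gini",
                   max_range: float = 5.0, n_sample: int | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """The per-service battery: five single-metric tests + three interaction terms.

    Returns one row per test (term, signed F, one- and two-sided p,
    Hochberg-corrected significance with family size ``m_tests``).  When
    ``n_sample`` is given and exceeded, each test runs through the
    convergence bootstrap at that standardized sample size.
    """
    transforms = {**DEFAULT_METRIC_TRANSFORMS, **(transforms or {})}
    y = np.asarray(D_per_point, dtype=float)
    pts = np.asarray(centroids, dtype=float)
    auto = auto_covariate(pts, y, max_range)
    rows = []

    def run(fit, n_params):
        if n_sample is not None and y.size >= n_sample:
            return convergence_bootstrap(fit, y, n_sample=n_sample, seed=seed,
                                         n_params=n_params)
        return fit(np.arange(y.size))

    for col in metrics.columns:
        kind, scale = transforms.get(col, ("none", None))
        mt = transform_metric(metrics[col].to_numpy(), kind, scale)

        def fit_single(idx, mt=mt):
            d = DriverDesign(y[idx], pts[idx], mt[idx], auto=auto[idx])
            return driver_anova(d)

        res = run(fit_single, n_params=3)
        f = res.factor("Metric")
        rows.append({"model": "single", "term": col, "F": f.F,
                     "F_signed": f.F_signed, "p_one": f.p_one, "p_two": f.p_two,
                     "converged": res.converged})

    if gdp_col not in metrics.columns or equality_col not in metrics.columns:
        raise ValueError("metrics table lacks the interaction-model columns")
    g_raw = metrics[gdp_col].to_numpy()
    e_raw = metrics[equality_col].to_numpy()
    g_kind, g_scale = transforms.get(gdp_col, ("log10", None))
    e_kind, e_scale = transforms.get(equality_col, ("arcsine", None))
    gt = transform_metric(g_raw, g_kind, g_scale)
    et = transform_metric(e_raw, e_kind, e_scale)

    def fit_inter(idx):
        return interaction_model(y[idx], pts[idx], gt[idx], et[idx],
                                 auto=auto[idx], gdp_transform="none",
                                 equality_transform="none")

    res = run(fit_inter, n_params=5)
    for term, label in (("GDP", f"{gdp_col} (interaction)"),
                        ("Equality", f"{equality_col} (interaction)"),
                        ("GDPxEquality", f"{gdp_col} x {equality_col}")):
        f = res.factor(term)
        rows.append({"model": "interaction", "term": label, "F": f.F,
                     "F_signed": f.F_signed, "p_one": f.p_one, "p_two": f.p_two,
                     "converged": res.converged})

    table = pd.DataFrame(rows)
    m = max(m_tests, len(table))
    table["significant"] = hochberg_correct(table["p_one"].to_numpy(),
                                            alpha=alpha, m=m)
    return table
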