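"""Configuration-driven orchestration of the six-stage analysis flow.

simulate -> harmonize -> normalize -> ensemble -> validate -> drivers

Each stage reads its inputs from the previous stage's files and writes plain
text (ASCII grids, CSV, GeoJSON, JSON), so any intermediate can be deleted
and regenerated byte-identically, and a completed stage whose outputs still
match the manifest checksums is skipped on rerun.  One global seed fans out
to per-stage seeds through numpy SeedSequence spawn keys, so every stage is
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drivers import driver_battery
from .ensemble import build_ensemble, renormalize_full_range, winsorise_raster
from .grids import (GridSpec, ModelStack, Raster, ValidationSet, ValidationUnit,
                    read_ascii_grid, write_ascii_grid)
from .harmonize import align, downscale_bilinear, upscale_mean
from .synthetic import (CountrySpec, WorldSpec, default_model_specs, gen_countries,
                        gen_model_outputs, gen_true_surface, gen_validation)
from .validation import (PredictionVector, bootstrap_compare, extract_predictions,
                         improvement_vs_random_model, score_predictor)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report",
           "simulate_country_accuracy", "simulate_plot_accuracy", "STAGES"]

STAGES = ("simulate", "harmonize", "normalize", "ensemble", "validate", "drivers")

_DEFAULTS = {
    "world": {"rows": 48, "cols": 48, "cell_size": 0.1, "correlation_length": 6.0},
    "models": {"k": 7, "noise_sd": 0.15, "bias_field_weight": 0.3,
               "shared_bias_weight": 0.1, "coverage_fraction": 1.0,
               "coarse_every": 3},
    "countries": {"n": 30, "coupling": 0.0, "coupled_metric": "hdi",
                  "obs_noise_sd": 0.0},
    "validation": {"kind": "polygon", "n_units": 30, "obs_noise_sd": 0.02,
                   "mode": "polygon_sum", "radius": None, "use_countries": True},
    "ensemble": {"statistic": "median"},
    "bootstrap": {"n_runs": 200, "rule": "fraction", "value": 0.5,
                  "replace": False, "alpha": 0.05},
    "drivers": {"n_sample": None, "alpha": 0.05, "m_tests": 8, "max_range": 5.0},
}


@dataclass
class RunConfig:
    """Fully serializable run description; a run is reproducible from it."""

    out_dir: str
    seed: int = 0
    world: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    countries: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    drivers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, defaults in _DEFAULTS.items():
            merged = {**defaults, **getattr(self, name)}
            unknown = set(merged) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
            setattr(self, name, merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Checksums, seeds and timing for every artifact a run wrote."""

    config: dict
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {relpath: sha256}
    seeds: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(100 + idx,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stage implementations (disk-to-disk)


def _write_validation_tables(vs: ValidationSet, out: Path, prefix: str) -> list[Path]:
    rows = []
    for u in vs.units:
        rows.append({
            "unit_id": u.unit_id, "kind": u.kind, "observed": u.observed,
            "centroid_x": u.centroid[0], "centroid_y": u.centroid[1],
            "pour_row": -1 if u.pour_point is None else u.pour_point[0],
            "pour_col": -1 if u.pour_point is None else u.pour_point[1],
        })
    files = []
    csv_path = out / f"{prefix}.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")
    files.append(csv_path)
    labels = Raster((vs.label_map if vs.label_map is not None else
                     np.full(vs.grid.shape, -1)).astype(float),
                    np.zeros(vs.grid.shape, dtype=bool), vs.grid)
    lab_path = out / f"{prefix}_labels.asc"
    write_ascii_grid(labels, lab_path, meta=vs.meta)
    files.append(lab_path)
    geo_path = out / f"{prefix}.geojson"
    vs.to_geojson(geo_path)
    files.append(geo_path)
    if vs.metrics is not None:
        m_path = out / f"{prefix}_metrics.csv"
        vs.metrics.to_csv(m_path, float_format="%.17g")
        files.append(m_path)
    return files


def _read_validation_tables(out: Path, prefix: str) -> ValidationSet:
    df = pd.read_csv(out / f"{prefix}.csv")
    labels_r = read_ascii_grid(out / f"{prefix}_labels.asc")
    labels = np.round(labels_r.values).astype(int)
    grid = labels_r.grid
    units = []
    for i, row in df.iterrows():
        cells = np.flatnonzero(labels.ravel() == i)
        pour = None
        if row["pour_row"] >= 0:
            pour = (int(row["pour_row"]), int(row["pour_col"]))
        units.append(ValidationUnit(
            unit_id=row["unit_id"], kind=row["kind"], observed=float(row["observed"]),
            centroid=(float(row["centroid_x"]), float(row["centroid_y"])),
            cells=cells if cells.size else None, pour_point=pour,
        ))
    metrics = None
    m_path = out / f"{prefix}_metrics.csv"
    if m_path.exists():
        metrics = pd.read_csv(m_path, index_col=0)
    return ValidationSet(kind=str(df["kind"].iloc[0]), grid=grid, units=units,
                         label_map=labels, metrics=metrics)


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    seed = _stage_seed(cfg.seed, "simulate")
    w = cfg.world
    world = WorldSpec(grid_rows=w["rows"], grid_cols=w["cols"],
                      cell_size=w["cell_size"],
                      correlation_length=w["correlation_length"], seed=seed)
    truth = gen_true_surface(world)
    m = cfg.models
    specs = default_model_specs(m["k"], noise_sd=m["noise_sd"],
                                bias_field_weight=m["bias_field_weight"],
                                shared_bias_weight=m["shared_bias_weight"],
                                coverage_fraction=m["coverage_fraction"])
    c = cfg.countries
    countries = gen_countries(
        CountrySpec(n_countries=c["n"], accuracy_coupling=c["coupling"],
                    coupled_metric=c["coupled_metric"]),
        world, seed=seed, truth=truth, obs_noise_sd=c["obs_noise_sd"])
    stack = gen_model_outputs(truth, specs, seed=seed,
                              noise_scale=countries.noise_scale)
    v = cfg.validation
    if v["use_countries"] and v["kind"] == "polygon":
        vs = countries
    else:
        vs = gen_validation(truth, v["kind"], v["n_units"], v["obs_noise_sd"],
                            seed=seed)

    sim = out / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    files = []
    write_ascii_grid(truth, sim / "truth.asc", meta={"seed": seed})
    files.append(sim / "truth.asc")
    coarse_every = max(0, int(m["coarse_every"]))
    for i, mid in enumerate(stack.ids):
        layer = stack[mid]
        native = "fine"
        if coarse_every and (i + 1) % coarse_every == 0:
            layer = upscale_mean(layer, 2)  # emulate a coarser native grid
            native = "coarse2"
        p = sim / f"model_{mid}.asc"
        write_ascii_grid(layer, p, meta={"seed": seed, "native": native})
        files.append(p)
    files += _write_validation_tables(vs, sim, "validation")
    if vs is not countries:
        files += _write_validation_tables(countries, sim, "countries")
    return files


def _target_grid(cfg: RunConfig) -> GridSpec:
    w = cfg.world
    return WorldSpec(grid_rows=w["rows"], grid_cols=w["cols"],
                     cell_size=w["cell_size"],
                     correlation_length=w["correlation_length"], seed=0).grid


def _stage_harmonize(cfg: RunConfig, out: Path) -> list[Path]:
    target = _target_grid(cfg)
    sim = out / "sim"
    rasters = {}
    for p in sorted(sim.glob("model_*.asc")):
        r = read_ascii_grid(p)
        if r.grid.cell_size > target.cell_size * 1.5:
            factor = int(round(r.grid.cell_size / target.cell_size))
            r = downscale_bilinear(r, factor)
        rasters[p.stem.removeprefix("model_")] = r
    stack = align(rasters, target)
    hdir = out / "harmonized"
    hdir.mkdir(exist_ok=True)
    files = []
    for mid in stack.ids:
        p = hdir / f"{mid}.asc"
        write_ascii_grid(stack[mid], p)
        files.append(p)
    n = Raster(stack.count().astype(float), np.zeros(target.shape, dtype=bool), target)
    write_ascii_grid(n, hdir / "n_models.asc")
    files.append(hdir / "n_models.asc")
    return files


def _stage_normalize(cfg: RunConfig, out: Path) -> list[Path]:
    hdir = out / "harmonized"
    ndir = out / "normalized"
    ndir.mkdir(exist_ok=True)
    files = []
    for p in sorted(hdir.glob("*.asc")):
        if p.stem == "n_models":
            continue
        r = read_ascii_grid(p)
        norm, params = winsorise_raster(r)
        q = ndir / p.name
        write_ascii_grid(norm, q, meta={"lower_cut": params.lower,
                                        "upper_cut": params.upper})
        files.append(q)
    return files


def _stage_ensemble(cfg: RunConfig, out: Path) -> list[Path]:
    ndir = out / "normalized"
    layers = {p.stem: read_ascii_grid(p) for p in sorted(ndir.glob("*.asc"))}
    stack = ModelStack(layers)
    ens = renormalize_full_range(build_ensemble(stack, cfg.ensemble["statistic"]))
    edir = out / "ensemble"
    edir.mkdir(exist_ok=True)
    files = []
    for name, r in (("ensemble", ens.values), ("sem", ens.sem),
                    ("n_models", ens.n_models)):
        p = edir / f"{name}.asc"
        write_ascii_grid(r, p, meta={"statistic": ens.statistic})
        files.append(p)
    return files


def _stage_validate(cfg: RunConfig, out: Path) -> list[Path]:
    seed = _stage_seed(cfg.seed, "validate")
    vs = _read_validation_tables(out / "sim", "validation")
    mode = cfg.validation["mode"]
    radius = cfg.validation["radius"]
    ens_r = read_ascii_grid(out / "ensemble" / "ensemble.asc")
    model_rs = {p.stem: read_ascii_grid(p)
                for p in sorted((out / "normalized").glob("*.asc"))}

    predictors = [PredictionVector("ensemble", extract_predictions(ens_r, vs, mode, radius).values)]
    for mid, r in model_rs.items():
        predictors.append(PredictionVector(mid, extract_predictions(r, vs, mode, radius).values))

    acc_rows = []
    per_point = {}
    model_accs = []
    ens_acc = None
    for pv in predictors:
        res = score_predictor(ens_r if pv.label == "ensemble" else model_rs[pv.label],
                              vs, mode, radius, label=pv.label)
        acc_rows.append({"predictor": pv.label, "overall": res.overall,
                         "spearman_rho": res.spearman_rho, "n": res.n})
        per_point[pv.label] = res.per_point
        if pv.label == "ensemble":
            ens_acc = res
        else:
            model_accs.append(res)
    improvement = improvement_vs_random_model(ens_acc, model_accs)

    b = cfg.bootstrap
    comp = bootstrap_compare(predictors, vs.observed, n_runs=b["n_runs"],
                             sample_rule=(b["rule"], b["value"]),
                             replace=b["replace"], alpha=b["alpha"], seed=seed)

    vdir = out / "validate"
    vdir.mkdir(exist_ok=True)
    files = []
    acc_df = pd.DataFrame(acc_rows)
    acc_df.to_csv(vdir / "accuracy.csv", index=False, float_format="%.17g")
    files.append(vdir / "accuracy.csv")
    pp = pd.DataFrame(per_point)
    pp.insert(0, "unit_id", [u.unit_id for u in vs.units][: len(pp)])
    pp.to_csv(vdir / "per_point.csv", index=False, float_format="%.17g")
    files.append(vdir / "per_point.csv")
    comp.pairs.to_csv(vdir / "comparison.csv", index=False, float_format="%.17g")
    files.append(vdir / "comparison.csv")
    summary = {
        "improvement_pct_points": improvement,
        "ensemble_overall": ens_acc.overall,
        "median_model_overall": float(np.median([m.overall for m in model_accs])),
        "bootstrap_mean_accuracy": dict(zip(comp.labels, map(float, comp.mean_accuracy))),
        "bootstrap_n_runs": comp.n_runs,
        "bootstrap_sample_size": comp.sample_size,
    }
    with open(vdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    files.append(vdir / "summary.json")
    return files


def _stage_drivers(cfg: RunConfig, out: Path) -> list[Path]:
    seed = _stage_seed(cfg.seed, "drivers")
    sim = out / "sim"
    prefix = "countries" if (sim / "countries.csv").exists() else "validation"
    countries = _read_validation_tables(sim, prefix)
    if countries.metrics is None:
        raise ValueError("driver stage needs country metrics")
    pp = pd.read_csv(out / "validate" / "per_point.csv")
    d = cfg.drivers
    if prefix == "validation":
        D = pp["ensemble"].to_numpy()
        centroids = countries.centroids[: len(D)]
        metrics = countries.metrics.iloc[: len(D)]
    else:
        # accuracy was scored on the country units themselves
        D = pp["ensemble"].to_numpy()
        centroids = countries.centroids
        metrics = countries.metrics
    table = driver_battery(D, centroids, metrics, alpha=d["alpha"],
                           m_tests=d["m_tests"], max_range=d["max_range"],
                           n_sample=d["n_sample"], seed=seed)
    ddir = out / "drivers"
    ddir.mkdir(exist_ok=True)
    p = ddir / "battery.csv"
    table.to_csv(p, index=False, float_format="%.17g")
    return [p]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "normalize": _stage_normalize,
    "ensemble": _stage_ensemble,
    "validate": _stage_validate,
    "drivers": _stage_drivers,
}


def run_pipeline(config: RunConfig, stages=STAGES, force: bool = False) -> RunManifest:
    """Execute the stages in order, skipping stages whose outputs are current.

    A stage is skipped when a previous manifest with the same configuration
    exists and every one of the stage's files is present with a matching
    checksum.  Failure halts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = None
    if manifest_path.exists():
        previous = RunManifest.load(manifest_path)
        if previous.config_hash != config.config_hash():
            previous = None
    manifest = RunManifest(config=config.to_dict(), config_hash=config.config_hash(),
                           version=__version__)
    if previous is not None:
        manifest.stages.update(previous.stages)
        manifest.seeds.update(previous.seeds)
    for stage in STAGES:
        if stage not in stages:
            continue
        if not force and previous is not None and stage in previous.stages:
            recorded = previous.stages[stage]
            if recorded and all((out / rel).exists() and _sha256(out / rel) == sha
                                for rel, sha in recorded.items()):
                continue
        t0 = time.perf_counter()
        try:
            files = _STAGE_FNS[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        checks = {}
        for f in files:
            rel = str(Path(f).relative_to(out))
            checks[rel] = _sha256(Path(f))
            side = Path(f).with_name(Path(f).name + ".json")
            if side.exists():
                checks[str(side.relative_to(out))] = _sha256(side)
        manifest.stages[stage] = checks
        manifest.seeds[stage] = _stage_seed(config.seed, stage)
        manifest.timing[stage] = round(time.perf_counter() - t0, 4)
        manifest.save(manifest_path)
    manifest.save(manifest_path)
    return manifest


def report(out_dir) -> str:
    """Human-readable run summary, regenerated from the files alone."""
    out = Path(out_dir)
    manifest = RunManifest.load(out / "manifest.json")
    lines = [f"esens run (version {manifest.version}, config {manifest.config_hash})",
             ""]
    acc_path = out / "validate" / "accuracy.csv"
    if acc_path.exists():
        acc = pd.read_csv(acc_path)
        with open(out / "validate" / "summary.json") as fh:
            summary = json.load(fh)
        lines.append("Accuracy (inverse of deviance) per predictor:")
        for _, row in acc.sort_values("overall", ascending=False).iterrows():
            lines.append(f"  {row['predictor']:<12} D = {row['overall']:.4f}"
                         f"  (Spearman rho = {row['spearman_rho']:+.3f}, n = {int(row['n'])})")
        lines.append(f"Ensemble vs median model: "
                     f"{summary['improvement_pct_points']:+.2f} percentage points")
        lines.append("")
    bat_path = out / "drivers" / "battery.csv"
    if bat_path.exists():
        bat = pd.read_csv(bat_path)
        lines.append("Driver tests (one-tailed F values, Hochberg-corrected):")
        for _, row in bat.iterrows():
            flag = " *" if row["significant"] else ""
            lines.append(f"  {row['term']:<28} F = {row['F_signed']:+8.2f}"
                         f"  p(one-sided) = {row['p_one']:.4f}{flag}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# One-call experiment used by calibration/power studies


def simulate_country_accuracy(world: WorldSpec, model_specs, country_spec: CountrySpec,
                              seed: int, obs_noise_sd: float = 0.0,
                              statistic: str = "median"):
    """Simulate one world and return per-country ensemble accuracy.

    Returns (accuracy_result, countries, ensemble_layer): the per-point
    inverse deviance of the renormalized committee ensemble scored on the
    country units, the country set (with metrics), and the ensemble layer.
    """
    world = dataclasses.replace(world, seed=seed)
    truth = gen_true_surface(world)
    countries = gen_countries(country_spec, world, seed=seed, truth=truth,
                              obs_noise_sd=obs_noise_sd)
    stack = gen_model_outputs(truth, model_specs, seed=seed,
                              noise_scale=countries.noise_scale)
    normalized = ModelStack({mid: winsorise_raster(stack[mid])[0]
                             for mid in stack.ids})
    ens = renormalize_full_range(build_ensemble(normalized, statistic))
    acc = score_predictor(ens.values, countries, "polygon_sum", label="ensemble")
    return acc, countries, ens


def simulate_plot_accuracy(world: WorldSpec, model_specs, country_spec: CountrySpec,
                           seed: int, plots_per_country: int = 3,
                           statistic: str = "median"):
    """Plot-scale accuracy per country: one D value from sampled plot cells.

    Emulates plot-based validation (e.g. forest inventory plots) attached to
    country-level covariates: in each country a few plot cells are sampled,
    the observation is the mean truth over them and the prediction the mean
    ensemble value; both vectors are Winsorised before the per-country
    inverse deviance is computed.  Compared with whole-country sums, this
    keeps unit sizes equal, so the per-unit error is governed by the local
    model noise — the route used in the driver calibration/power studies.

    Returns (D_per_country, countries, ensemble_layer).
    """
    world = dataclasses.replace(world, seed=seed)
    truth = gen_true_surface(world)
    countries = gen_countries(country_spec, world, seed=seed, truth=truth)
    stack = gen_model_outputs(truth, model_specs, seed=seed,
                              noise_scale=countries.noise_scale)
    normalized = ModelStack({mid: winsorise_raster(stack[mid])[0]
                             for mid in stack.ids})
    ens = renormalize_full_range(build_ensemble(normalized, statistic))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    ens_flat = ens.values.values.ravel()
    truth_flat = truth.values.ravel()
    obs, pred = [], []
    for u in countries.units:
        cells = np.asarray(u.cells)
        chosen = rng.choice(cells, size=min(plots_per_country, cells.size),
                            replace=False)
        obs.append(truth_flat[chosen].mean())
        pred.append(ens_flat[chosen].mean())
    from .validation import _normalize_vector

    X = _normalize_vector(np.asarray(obs))
    Y = _normalize_vector(np.asarray(pred))
    return 1.0 - np.abs(X - Y), countries, ens
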