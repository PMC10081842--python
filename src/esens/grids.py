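"""Core spatial containers and plain-text geospatial I/O.

Conventions (shared by every module):

* cell-centre registration, row 0 at the northern edge, x increasing east;
* grid indices are 0-based and extents are half-open intervals;
* ``nodata_mask`` is ``True`` where a cell carries *no data*.  True zeros are
  data and take part in every statistic; no-data cells are always ignored.

Rasters are serialized as ESRI ASCII grids (a plain-text format readable by
any GIS), validation units as GeoJSON.  Provenance (seeds, parameters) is
written to a ``.json`` sidecar next to each grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box, mapping
from shapely.ops import unary_union

__all__ = [
    "GridSpec",
    "Raster",
    "ModelStack",
    "ValidationUnit",
    "ValidationSet",
    "read_ascii_grid",
    "write_ascii_grid",
]

_DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    ``origin_x``/``origin_y`` locate the upper-left *corner* of cell (0, 0);
    ``cell_size`` is in decimal degrees.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates as two (n_rows, n_cols) arrays."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return xx, yy

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); raises if outside."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def cell_box(self, row: int, col: int):
        x0 = self.origin_x + col * self.cell_size
        y1 = self.origin_y - row * self.cell_size
        return box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(**{k: d[k] for k in ("origin_x", "origin_y", "cell_size", "n_rows", "n_cols")},
                   crs=d.get("crs", "EPSG:4326"))


@dataclass
class Raster:
    """A 2-D value grid with an explicit no-data mask on a :class:`GridSpec`."""

    values: np.ndarray
    nodata_mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.nodata_mask.shape != self.grid.shape:
            raise ValueError("values / nodata_mask shape does not match the grid")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values found outside the no-data mask")

    @classmethod
    def from_values(cls, values: np.ndarray, grid: GridSpec) -> "Raster":
        """Raster from an array where NaN encodes no-data."""
        values = np.asarray(values, dtype=float)
        mask = ~np.isfinite(values)
        vals = np.where(mask, 0.0, values)
        return cls(vals, mask, grid)

    @classmethod
    def full(cls, grid: GridSpec, fill: float = 0.0, nodata: bool = False) -> "Raster":
        return cls(
            np.full(grid.shape, fill, dtype=float),
            np.full(grid.shape, nodata, dtype=bool),
            grid,
        )

    @property
    def data_values(self) -> np.ndarray:
        """1-D array of the data cells (no-data excluded)."""
        return self.values[~self.nodata_mask]

    @property
    def n_data(self) -> int:
        return int(np.count_nonzero(~self.nodata_mask))

    def nan_values(self) -> np.ndarray:
        """Dense array with NaN at no-data cells."""
        return np.where(self.nodata_mask, np.nan, self.values)

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Raster":
        mask = self.nodata_mask if nodata_mask is None else nodata_mask
        return Raster(np.array(values, dtype=float), np.array(mask, dtype=bool), self.grid)

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.nodata_mask.copy(), self.grid)


class ModelStack:
    """A set of Rasters on one common grid, keyed by model id."""

    def __init__(self, layers: Mapping[str, Raster]):
        if not layers:
            raise ValueError("a ModelStack needs at least one layer")
        ids = list(layers)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate model ids")
        grid = next(iter(layers.values())).grid
        for mid, r in layers.items():
            if not r.grid.approx_equal(grid):
                raise ValueError(f"layer {mid!r} is not on the common grid")
        self.layers: dict[str, Raster] = dict(layers)
        self.grid = grid

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, model_id: str) -> Raster:
        return self.layers[model_id]

    @property
    def ids(self) -> list[str]:
        return list(self.layers)

    def as_array(self) -> np.ndarray:
        """(K, n_rows, n_cols) array with NaN at no-data cells."""
        return np.stack([r.nan_values() for r in self.layers.values()])

    def count(self) -> np.ndarray:
        """Per-cell number of contributing (non-no-data) model layers."""
        return np.sum([~r.nodata_mask for r in self.layers.values()], axis=0).astype(int)

    def map(self, fn) -> "ModelStack":
        return ModelStack({mid: fn(r) for mid, r in self.layers.items()})


# ---------------------------------------------------------------------------
# Validation units


@dataclass
class ValidationUnit:
    """One validation unit: a point, polygon or catchment with one observation."""

    unit_id: str
    kind: str  # point | polygon | catchment
    observed: float
    centroid: tuple[float, float]
    cells: np.ndarray | None = None  # flat indices into the grid
    geometry: object | None = None  # shapely geometry, built lazily for cells
    pour_point: tuple[int, int] | None = None  # (row, col), catchments only


@dataclass
class ValidationSet:
    """Validation units on a grid, with optional country-level covariates.

    ``label_map`` (unit index per cell, -1 elsewhere) enables exact, fast
    zonal statistics for units that were defined as cell sets.
    ``noise_scale`` carries the per-cell model-noise multiplier that couples
    development metrics to local accuracy in synthetic country worlds.
    """

    kind: str
    grid: GridSpec
    units: list[ValidationUnit]
    label_map: np.ndarray | None = None
    metrics: pd.DataFrame | None = None
    noise_scale: Raster | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.units)

    @property
    def observed(self) -> np.ndarray:
        return np.array([u.observed for u in self.units], dtype=float)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([u.centroid for u in self.units], dtype=float)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def geometry(self, i: int):
        """Shapely geometry of unit *i*, built from its cell set on demand."""
        u = self.units[i]
        if u.geometry is None:
            if u.cells is None:
                raise ValueError(f"unit {u.unit_id!r} has neither geometry nor cells")
            rows, cols = np.unravel_index(np.asarray(u.cells), self.grid.shape)
            u.geometry = unary_union([self.grid.cell_box(r, c) for r, c in zip(rows, cols)])
        return u.geometry

    def to_geojson(self, path) -> None:
        feats = []
        for i, u in enumerate(self.units):
            geom = self.geometry(i) if (u.cells is not None or u.geometry is not None) else Point(u.centroid)
            props = {"unit_id": u.unit_id, "kind": u.kind, "observed": u.observed}
            if u.pour_point is not None:
                props["pour_point"] = list(u.pour_point)
            if self.metrics is not None and u.unit_id in self.metrics.index:
                props.update({k: float(v) for k, v in self.metrics.loc[u.unit_id].items()})
            feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
        doc = {"type": "FeatureCollection", "features": feats, "metadata": dict(self.meta)}
        with open(path, "w") as fh:
            json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI ASCII grid)


def write_ascii_grid(r: Raster, path, nodata_value: float = _DEFAULT_NODATA,
                     meta: Mapping | None = None) -> None:
    """Write a Raster as an ESRI ASCII grid; provenance goes to a sidecar."""
    g = r.grid
    vals = np.where(r.nodata_mask, nodata_value, r.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")  # full round-trip precision
    if meta is not None:
        with open(f"{path}.json", "w") as fh:
            json.dump({"crs": g.crs, **dict(meta)}, fh, indent=1, sort_keys=True)


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"grid body shape {values.shape} does not match header")
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    mask = values == nodata
    return Raster(np.where(mask, 0.0, values), mask, grid)


def cells_within_radius(grid: GridSpec, x: float, y: float, radius: float) -> np.ndarray:
    """Flat indices of cells whose centres lie within ``radius`` degrees of (x, y)."""
    xx, yy = grid.center_grids()
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    return np.flatnonzero(d2.ravel() <= radius**2 + 1e-12)


def polygon_cell_indices(grid: GridSpec, geom) -> np.ndarray:
    """Flat indices of cells whose centres are covered by ``geom``.

    Cell-centre membership makes zonal sums exactly conservative over any
    partition of the grid into polygons built from cell boundaries.
    """
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(np.floor((minx - grid.origin_x) / grid.cell_size)) - 1)
    c1 = min(grid.n_cols, int(np.ceil((maxx - grid.origin_x) / grid.cell_size)) + 1)
    r0 = max(0, int(np.floor((grid.origin_y - maxy) / grid.cell_size)) - 1)
    r1 = min(grid.n_rows, int(np.ceil((grid.origin_y - miny) / grid.cell_size)) + 1)
    if c0 >= c1 or r0 >= r1:
        return np.array([], dtype=int)
    xs = grid.x_centers[c0:c1]
    ys = grid.y_centers[r0:r1]
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel())
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    flat = rows.ravel() * grid.n_cols + cols.ravel()
    return flat[inside]
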