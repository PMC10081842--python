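"""Bring model-output rasters of differing resolution onto one common grid.

Upscaling (coarsening) takes the block mean with no-data cells ignored;
downscaling (refining) interpolates bilinearly between the four nearest
coarse cell centres, with edge cells clamped to nearest-centre extrapolation.
A fine cell becomes no-data if any coarse centre that actually contributes
(weight > 0) is no-data — no values are invented at data edges.

All rasters are assumed to share one geographic CRS; alignment shifts layers
by whole cells onto the target grid (no reprojection, no sub-cell shifts).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .grids import GridSpec, ModelStack, Raster

__all__ = ["upscale_mean", "downscale_bilinear", "align", "apply_landuse_mask"]


def upscale_mean(r: Raster, factor: int) -> Raster:
    """Coarsen by an integer factor, each coarse cell the mean of its block.

    No-data members are ignored; a coarse cell is no-data only when all its
    members are.  Dimensions not divisible by the factor are padded with
    no-data before blocking.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    g = r.grid
    rows_out = -(-g.n_rows // factor)
    cols_out = -(-g.n_cols // factor)
    pad_r, pad_c = rows_out * factor - g.n_rows, cols_out * factor - g.n_cols
    vals = np.pad(np.where(r.nodata_mask, 0.0, r.values), ((0, pad_r), (0, pad_c)))
    data = np.pad(~r.nodata_mask, ((0, pad_r), (0, pad_c)))
    blocks_sum = vals.reshape(rows_out, factor, cols_out, factor).sum(axis=(1, 3))
    blocks_n = data.reshape(rows_out, factor, cols_out, factor).sum(axis=(1, 3))
    mask = blocks_n == 0
    out = np.divide(blocks_sum, blocks_n, out=np.zeros_like(blocks_sum), where=~mask)
    grid = GridSpec(g.origin_x, g.origin_y, g.cell_size * factor, rows_out, cols_out, g.crs)
    return Raster(out, mask, grid)


def _axis_weights(n_out: int, n_in: int, factor: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lower index, upper index and upper weight along one axis.

    Fine centre i maps to fractional coarse index (i + 0.5)/factor - 0.5,
    clipped into [0, n_in - 1] (nearest-centre clamping at the edges).
    """
    frac = np.clip((np.arange(n_out) + 0.5) / factor - 0.5, 0.0, n_in - 1.0)
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    i1 = np.minimum(i0 + 1, n_in - 1)
    return i0, i1, t


def bilinear_sample(r: Raster, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the bilinear interpolant of ``r`` at arbitrary coordinates.

    Returns (values, nodata) arrays.  Coordinates beyond the outermost cell
    centres are clamped.  A sample is no-data if any centre with positive
    weight is no-data.
    """
    g = r.grid
    fx = np.clip((np.asarray(x, float) - g.origin_x) / g.cell_size - 0.5, 0.0, g.n_cols - 1.0)
    fy = np.clip((g.origin_y - np.asarray(y, float)) / g.cell_size - 0.5, 0.0, g.n_rows - 1.0)
    c0 = np.floor(fx).astype(int)
    tx = fx - c0
    c1 = np.minimum(c0 + 1, g.n_cols - 1)
    r0 = np.floor(fy).astype(int)
    ty = fy - r0
    r1 = np.minimum(r0 + 1, g.n_rows - 1)

    w00 = (1 - ty) * (1 - tx)
    w01 = (1 - ty) * tx
    w10 = ty * (1 - tx)
    w11 = ty * tx
    vals = (w00 * r.values[r0, c0] + w01 * r.values[r0, c1]
            + w10 * r.values[r1, c0] + w11 * r.values[r1, c1])
    m = r.nodata_mask
    bad = ((w00 > 0) & m[r0, c0]) | ((w01 > 0) & m[r0, c1]) \
        | ((w10 > 0) & m[r1, c0]) | ((w11 > 0) & m[r1, c1])
    return np.where(bad, 0.0, vals), bad


def downscale_bilinear(r: Raster, factor: int) -> Raster:
    """Refine by an integer factor via bilinear interpolation of cell centres."""
    if factor < 2:
        raise ValueError("factor must be >= 2")
    g = r.grid
    grid = GridSpec(g.origin_x, g.origin_y, g.cell_size / factor,
                    g.n_rows * factor, g.n_cols * factor, g.crs)
    xx, yy = grid.center_grids()
    vals, mask = bilinear_sample(r, xx, yy)
    return Raster(vals, mask, grid)


def align(rasters: Sequence[Raster] | Mapping[str, Raster], target: GridSpec) -> ModelStack:
    """Clip/pad rasters onto the target grid; returns a stack with counts.

    Layers must already share the target's cell size and grid registration
    (resample first with :func:`upscale_mean` / :func:`downscale_bilinear`);
    they may cover a different extent, shifted by whole cells.
    """
    if isinstance(rasters, Mapping):
        items = list(rasters.items())
    else:
        items = [(f"layer_{i:02d}", r) for i, r in enumerate(rasters)]
    if not items:
        raise ValueError("empty input list")
    layers: dict[str, Raster] = {}
    for mid, r in items:
        g = r.grid
        if abs(g.cell_size - target.cell_size) > 1e-9:
            raise ValueError(f"layer {mid!r}: cell size {g.cell_size} != target "
                             f"{target.cell_size}; resample first")
        off_c = (g.origin_x - target.origin_x) / target.cell_size
        off_r = (target.origin_y - g.origin_y) / target.cell_size
        if abs(off_c - round(off_c)) > 1e-6 or abs(off_r - round(off_r)) > 1e-6:
            raise ValueError(f"layer {mid!r} is not registered to the target grid")
        off_c, off_r = int(round(off_c)), int(round(off_r))
        vals = np.zeros(target.shape)
        mask = np.ones(target.shape, dtype=bool)
        # overlap window in target coordinates
        tr0, tr1 = max(0, off_r), min(target.n_rows, off_r + g.n_rows)
        tc0, tc1 = max(0, off_c), min(target.n_cols, off_c + g.n_cols)
        if tr0 < tr1 and tc0 < tc1:
            sr0, sc0 = tr0 - off_r, tc0 - off_c
            sr1, sc1 = sr0 + (tr1 - tr0), sc0 + (tc1 - tc0)
            vals[tr0:tr1, tc0:tc1] = r.values[sr0:sr1, sc0:sc1]
            mask[tr0:tr1, tc0:tc1] = r.nodata_mask[sr0:sr1, sc0:sc1]
        layers[mid] = Raster(vals, mask, target)
    return ModelStack(layers)


def apply_landuse_mask(r: Raster, mask: Raster, keep_classes: set) -> Raster:
    """Keep cells whose land-use class is in ``keep_classes``; rest no-data.

    Used to derive fuelwood/forage proxies from carbon layers by restricting
    them to woody or grassland cells.  No-data cells of the class raster are
    treated as not kept.
    """
    if not mask.grid.approx_equal(r.grid):
        raise ValueError("land-use mask is not on the raster's grid")
    classes = np.round(mask.values).astype(int)
    keep = np.isin(classes, list(keep_classes)) & ~mask.nodata_mask
    new_mask = r.nodata_mask | ~keep
    return Raster(np.where(new_mask, 0.0, r.values), new_mask, r.grid)
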