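import numpy as np
import pytest

from esens.grids import GridSpec, Raster


@pytest.fixture
def grid8() -> GridSpec:
    return GridSpec(origin_x=0.0, origin_y=8.0, cell_size=1.0, n_rows=8, n_cols=8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_raster(values, nodata=None, origin=(0.0, None), cell_size=1.0) -> Raster:
    """Raster from a 2-D list/array; ``nodata`` is a boolean array or None."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    origin_y = origin[1] if origin[1] is not None else n_rows * cell_size
    grid = GridSpec(origin_x=origin[0], origin_y=origin_y, cell_size=cell_size,
                    n_rows=n_rows, n_cols=n_cols)
    mask = np.zeros(values.shape, dtype=bool) if nodata is None else np.asarray(nodata, bool)
    return Raster(np.where(mask, 0.0, values), mask, grid)
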