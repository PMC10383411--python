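import numpy as np
import pytest

from paddyrisk.raster_core import Raster
from paddyrisk.synthetic_data import FieldConfig


@pytest.fixture
def small_config() -> FieldConfig:
    """Reduced field for fast tests: default noise levels, smaller extent/GSD."""
    return FieldConfig(width=12.0, height=16.0, band_cell_size=0.1,
                       elevation_cell_size=0.1, san_correlation_length=3.0,
                       mixel_patch_length=1.5, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def make_raster(values, cell_size=1.0, origin=(0.0, None), mask=None) -> Raster:
    """Raster helper; default origin puts the grid's top-left at (0, n_rows)."""
    values = np.asarray(values, dtype=float)
    ox, oy = origin
    if oy is None:
        oy = values.shape[0] * cell_size
    return Raster(values, cell_size, (ox, oy), mask)


def oracle_circle_mean(r: Raster, cx: float, cy: float, radius: float):
    """Exhaustive pixel-centre loop: the independent zonal-statistics oracle."""
    total, n = 0.0, 0
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            px = r.origin[0] + (j + 0.5) * r.cell_size
            py = r.origin[1] - (i + 0.5) * r.cell_size
            if (px - cx) ** 2 + (py - cy) ** 2 <= radius**2 and not r.nodata_mask[i, j]:
                total += r.values[i, j]
                n += 1
    return (total / n if n else float("nan")), n


def oracle_mesh_means(r: Raster, grid) -> dict:
    """Exhaustive assignment of pixel centres to half-open mesh cells."""
    ax, ay = grid.anchor
    cells = {(int(ix), int(iy)): mid for mid, ix, iy in
             zip(grid.cells["mesh_id"], grid.cells["ix"], grid.cells["iy"])}
    acc: dict[int, list] = {}
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if r.nodata_mask[i, j]:
                continue
            px = r.origin[0] + (j + 0.5) * r.cell_size
            py = r.origin[1] - (i + 0.5) * r.cell_size
            key = (int(np.floor((px - ax) / grid.cell_size)),
                   int(np.floor((py - ay) / grid.cell_size)))
            if key in cells:
                acc.setdefault(cells[key], []).append(r.values[i, j])
    return {mid: float(np.mean(v)) for mid, v in acc.items()}
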