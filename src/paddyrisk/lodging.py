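"""Canopy-height analysis of rice lodging.

The canopy height model (CHM) is the surface model minus the terrain model.
With r the seasonal-maximum CHM and y the harvest CHM (plant length assumed
unchanged between the two dates), the height drop is dCHM = r - y and the
stem inclination angle is theta = arcsin(y / r): 90 deg upright, 0 deg flat.
Severity is scored on a six-level scale in 18-degree increments, level 0
(no lodging, theta > 72) through level 5 (completely lodged, theta = 0).

No height-bias correction is applied to the CHM: a constant photogrammetric
underestimate cancels in dCHM and shifts theta only a few degrees, which is
small against the 18-degree class width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster_core import (AlignmentError, BufferZone, MeshGrid, Raster,
                          raster_subtract, zonal_mean_circle, zonal_mean_mesh)

__all__ = [
    "R_MIN_DEFAULT",
    "compute_chm",
    "delta_chm",
    "inclination_angle",
    "lodging_level",
    "lodging_mesh_map",
    "chm_vs_measured",
]

#: minimum plausible maximum-CHM (m); cells below are treated as bare ground
R_MIN_DEFAULT = 0.05


def compute_chm(dsm: Raster, dtm: Raster) -> Raster:
    """Canopy height model DSM - DTM, clamped below at zero.

    Negative differences arise from photogrammetric noise on bare or sparse
    patches and carry no physical meaning as plant height.
    """
    diff = raster_subtract(dsm, dtm)
    return diff.with_values(np.where(diff.nodata_mask, np.nan,
                                     np.maximum(diff.values, 0.0)))


def delta_chm(r_chm: Raster, y_chm: Raster) -> Raster:
    """Height drop between seasonal maximum and harvest, r − y, clamped at 0."""
    diff = raster_subtract(r_chm, y_chm)
    return diff.with_values(np.where(diff.nodata_mask, np.nan,
                                     np.maximum(diff.values, 0.0)))


def inclination_angle(r_chm: Raster, y_chm: Raster,
                      r_min: float = R_MIN_DEFAULT) -> Raster:
    """Inclination angle arcsin(y/r) in degrees.

    The ratio is clipped to [0, 1] before the arcsine (noise can push
    y slightly above r); pixels with maximum CHM below ``r_min`` are set to
    nodata — there is no crop whose angle could be measured.
    """
    if not r_chm.aligned_with(y_chm):
        raise AlignmentError("r and y canopy models are not aligned")
    mask = r_chm.nodata_mask | y_chm.nodata_mask | (r_chm.values < r_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(y_chm.values / r_chm.values, 0.0, 1.0)
    theta = np.degrees(np.arcsin(np.where(mask, 0.0, ratio)))
    return Raster(np.where(mask, np.nan, theta), r_chm.cell_size,
                  r_chm.origin, mask)


def lodging_level(theta) -> np.ndarray | int:
    """Six-level lodging severity from the inclination angle.

    Levels partition [0, 90] deg into 18-degree half-open classes:
    0 for (72, 90], 1 for (54, 72], 2 for (36, 54], 3 for (18, 36],
    4 for (0, 18], and 5 only at exactly 0 deg (completely lodged).
    """
    arr = np.asarray(theta, dtype=float)
    if np.any((arr < 0) | (arr > 90)):
        raise ValueError("inclination angle must lie in [0, 90] degrees")
    levels = np.where(arr == 0, 5, 5 - np.ceil(arr / 18.0)).astype(int)
    return levels if levels.ndim else int(levels)


@dataclass
class LodgingRecord:
    """Per-mesh-cell lodging summary."""

    mesh_id: int
    delta_chm: float
    theta: float
    level: int
    is_edge: bool


def lodging_mesh_map(theta: Raster, delta: Raster, grid: MeshGrid) -> pd.DataFrame:
    """Aggregate per-pixel angle and height drop onto the mesh.

    Each cell receives the mean of its valid pixels; the severity level is
    computed from the cell-mean angle.  Cells with no valid pixel are kept
    with a missing flag.  Columns: ``mesh_id, x, y, delta_chm, theta,
    level, is_edge, missing``.
    """
    t = zonal_mean_mesh(theta, grid).rename(columns={"value": "theta"})
    d = zonal_mean_mesh(delta, grid).rename(columns={"value": "delta_chm"})
    out = grid.cells[["mesh_id", "x", "y", "is_edge"]].merge(
        t[["mesh_id", "theta"]], on="mesh_id").merge(
        d[["mesh_id", "delta_chm"]], on="mesh_id")
    out["missing"] = out["theta"].isna() | out["delta_chm"].isna()
    ok = ~out["missing"]
    levels = np.full(len(out), -1, dtype=int)
    levels[ok.to_numpy()] = lodging_level(
        np.clip(out.loc[ok, "theta"].to_numpy(), 0.0, 90.0))
    out["level"] = levels
    return out[["mesh_id", "x", "y", "delta_chm", "theta", "level",
                "is_edge", "missing"]]


def chm_vs_measured(chm: Raster, survey: pd.DataFrame,
                    radius: float = 0.15) -> dict:
    """Compare buffer-mean CHM with field-measured plant height.

    ``survey`` needs columns ``x, y, height`` (m).  Returns the mean bias
    (CHM − measured), the Pearson correlation across points (NaN with a
    flag when fewer than two points), and the per-point table.
    """
    rows = []
    for rec in survey.itertuples(index=False):
        mean, n = zonal_mean_circle(chm, BufferZone((rec.x, rec.y), radius))
        rows.append((rec.x, rec.y, rec.height, mean, n))
    table = pd.DataFrame(rows, columns=["x", "y", "measured", "chm", "n_pixels"])
    diff = table["chm"] - table["measured"]
    result = {
        "n": len(table),
        "mean_bias": float(diff.mean()),
        "correlation": float("nan"),
        "correlation_defined": len(table) >= 2,
        "table": table,
    }
    if len(table) >= 2 and table["measured"].std() > 0 and table["chm"].std() > 0:
        result["correlation"] = float(
            stats.pearsonr(table["measured"], table["chm"]).statistic)
    else:
        result["correlation_defined"] = False
    return result
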