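"""Raster data model, algebra, zonal statistics and GeoTIFF/vector I/O.

Coordinate convention: planar metres, x east, y north.  The raster origin is
the top-left *corner*; rows increase southward, so pixel (i, j) has its
centre at ``(origin_x + (j + 0.5) * cell_size, origin_y - (i + 0.5) * cell_size)``.
This matches the usual north-up GeoTIFF affine.

Zone membership is by pixel centre (no area weighting), the behaviour of
standard GIS zone-statistics tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from shapely import wkt as _wkt
from shapely.geometry import Point, Polygon

__all__ = [
    "Raster",
    "FieldBoundary",
    "MeshGrid",
    "BufferZone",
    "AlignmentError",
    "EmptyZoneError",
    "RasterFormatError",
    "raster_subtract",
    "make_mesh_grid",
    "zonal_mean_circle",
    "zonal_mean_mesh",
    "load_raster",
    "save_raster",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113
_GEO_KEY_DIRECTORY = 34735


class AlignmentError(ValueError):
    """Raised when two rasters do not share shape, origin and cell size."""


class EmptyZoneError(ValueError):
    """Raised when a zone contains no valid (non-nodata) pixel centres."""


class RasterFormatError(ValueError):
    """Raised for unreadable or ungeoreferenced raster files."""


@dataclass
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values
        2-D array of cell values.  Units depend on content: metres for
        elevation models, dimensionless reflectance-scaled DN for spectral
        bands, mg N kg^-1 for nitrogen maps.
    cell_size
        Ground size of one (square) pixel in metres.
    origin
        Planar (x, y) of the top-left corner of the grid, metres.
    nodata_mask
        Boolean array, True where the pixel carries no data.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def aligned_with(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate arrays, each shaped like ``values``."""
        n_rows, n_cols = self.shape
        cs = self.cell_size
        xs = self.origin[0] + (np.arange(n_cols) + 0.5) * cs
        ys = self.origin[1] - (np.arange(n_rows) + 0.5) * cs
        return np.broadcast_to(xs, self.shape).copy(), np.broadcast_to(
            ys[:, None], self.shape
        ).copy()

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the pixels containing points (x, y)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        """New raster on the same grid with different values."""
        m = self.nodata_mask if mask is None else (mask | self.nodata_mask)
        return Raster(values, self.cell_size, self.origin, m.copy())


@dataclass
class FieldBoundary:
    """Field outline as a closed planar polygon (metres)."""

    polygon: Polygon

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("boundary polygon must enclose a positive area")
        if not self.polygon.is_valid:
            raise ValueError("boundary polygon is self-intersecting or invalid")

    @classmethod
    def rectangle(cls, width: float, height: float, x0: float = 0.0, y0: float = 0.0
                  ) -> "FieldBoundary":
        """Axis-aligned rectangle with its lower-left corner at (x0, y0)."""
        return cls(Polygon([(x0, y0), (x0 + width, y0),
                            (x0 + width, y0 + height), (x0, y0 + height)]))

    @classmethod
    def from_wkt(cls, text: str) -> "FieldBoundary":
        return cls(_wkt.loads(text))

    def to_wkt(self) -> str:
        return self.polygon.wkt

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds


@dataclass
class BufferZone:
    """Circular zone used for point-centred zonal statistics."""

    centre: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("buffer radius must be positive")


@dataclass
class MeshGrid:
    """Square mesh clipped to a field boundary.

    Cells are half-open squares [x, x+s) x [y, y+s) anchored at the
    boundary's minimum corner; a cell belongs to the grid iff its centre
    lies inside the boundary, and is flagged *edge* iff the centre is within
    ``edge_width`` of the boundary outline.
    """

    cell_size: float
    edge_width: float
    anchor: tuple[float, float]
    cells: pd.DataFrame  # columns: mesh_id, ix, iy, x, y, is_edge

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_edge(self) -> int:
        return int(self.cells["is_edge"].sum())

    @property
    def n_inside(self) -> int:
        return self.n_cells - self.n_edge


def raster_subtract(a: Raster, b: Raster) -> Raster:
    """Per-pixel a − b on aligned grids; nodata propagates from either input."""
    _require_aligned(a, b)
    mask = a.nodata_mask | b.nodata_mask
    values = np.where(mask, np.nan, a.values - b.values)
    return Raster(values, a.cell_size, a.origin, mask)


def _require_aligned(a: Raster, b: Raster) -> None:
    if not a.aligned_with(b):
        raise AlignmentError(
            f"rasters not aligned: shapes {a.shape}/{b.shape}, "
            f"origins {a.origin}/{b.origin}, cell {a.cell_size}/{b.cell_size}"
        )


def make_mesh_grid(boundary: FieldBoundary, cell_size: float = 1.0,
                   edge_width: float = 4.0) -> MeshGrid:
    """Tile the boundary's bounding box with half-open square cells.

    Only cells whose centre falls inside the polygon are kept; the edge flag
    is set where the Euclidean distance from the centre to the boundary
    outline is below ``edge_width``.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    if edge_width < 0:
        raise ValueError("edge_width must be non-negative")
    minx, miny, maxx, maxy = boundary.bounds
    n_x = int(np.ceil((maxx - minx) / cell_size - 1e-12))
    n_y = int(np.ceil((maxy - miny) / cell_size - 1e-12))
    if n_x == 0 or n_y == 0:
        raise ValueError("degenerate boundary: bounding box has zero extent")

    ix, iy = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    cx = minx + (ix + 0.5) * cell_size
    cy = miny + (iy + 0.5) * cell_size

    poly = boundary.polygon
    outline = poly.exterior
    keep = np.fromiter((poly.contains(Point(x, y)) for x, y in zip(cx, cy)),
                       dtype=bool, count=len(cx))
    ix, iy, cx, cy = ix[keep], iy[keep], cx[keep], cy[keep]
    if edge_width > 0:
        dist = np.fromiter((outline.distance(Point(x, y)) for x, y in zip(cx, cy)),
                           dtype=float, count=len(cx))
        is_edge = dist < edge_width
    else:
        is_edge = np.zeros(len(cx), dtype=bool)

    cells = pd.DataFrame({
        "mesh_id": np.arange(len(cx)),
        "ix": ix, "iy": iy, "x": cx, "y": cy, "is_edge": is_edge,
    })
    return MeshGrid(cell_size=cell_size, edge_width=edge_width,
                    anchor=(minx, miny), cells=cells)


def zonal_mean_circle(r: Raster, zone: BufferZone) -> tuple[float, int]:
    """Mean over valid pixels whose centres fall within the circle.

    Returns ``(mean, n_pixels)``; raises :class:`EmptyZoneError` when no
    valid centre lies inside.
    """
    cx, cy = zone.centre
    rad = zone.radius
    # restrict to the bounding window of the circle
    row0, col0 = r.index_of(cx - rad, cy + rad)
    row1, col1 = r.index_of(cx + rad, cy - rad)
    row0 = max(int(row0), 0)
    col0 = max(int(col0), 0)
    row1 = min(int(row1) + 1, r.shape[0])
    col1 = min(int(col1) + 1, r.shape[1])
    if row0 >= row1 or col0 >= col1:
        raise EmptyZoneError("buffer circle lies outside the raster extent")

    cs = r.cell_size
    xs = r.origin[0] + (np.arange(col0, col1) + 0.5) * cs
    ys = r.origin[1] - (np.arange(row0, row1) + 0.5) * cs
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    inside = dy2[:, None] + dx2[None, :] <= rad * rad
    window = r.values[row0:row1, col0:col1]
    valid = inside & ~r.nodata_mask[row0:row1, col0:col1]
    n = int(valid.sum())
    if n == 0:
        raise EmptyZoneError("no valid pixel centres inside the buffer circle")
    return float(window[valid].mean()), n


def zonal_mean_mesh(r: Raster, grid: MeshGrid) -> pd.DataFrame:
    """Per-cell mean over pixels whose centres fall in each half-open cell.

    Returns a frame with columns ``mesh_id, value, n_pixels, missing``;
    cells containing no valid pixel are flagged missing (value NaN).
    """
    px, py = r.pixel_centres()
    ax, ay = grid.anchor
    cs = grid.cell_size
    jx = np.floor((px - ax) / cs).astype(int)
    jy = np.floor((py - ay) / cs).astype(int)

    key_of_cell = {(int(i), int(j)): mid for mid, i, j in
                   zip(grid.cells["mesh_id"], grid.cells["ix"], grid.cells["iy"])}
    valid = ~r.nodata_mask
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    # bucket by integer cell index; vectorised accumulation over unique keys
    flat_key = jx.ravel().astype(np.int64) * (2**32) + (jy.ravel().astype(np.int64) & 0xFFFFFFFF)
    vals = r.values.ravel()
    ok = valid.ravel() & np.isfinite(vals)
    uniq, inv = np.unique(flat_key[ok], return_inverse=True)
    s = np.bincount(inv, weights=vals[ok], minlength=len(uniq))
    c = np.bincount(inv, minlength=len(uniq))
    for k, sv, cv in zip(uniq, s, c):
        i = int(k >> 32)
        j = int(np.int32(k & 0xFFFFFFFF))
        mid = key_of_cell.get((i, j))
        if mid is not None:
            sums[mid] = float(sv)
            counts[mid] = int(cv)

    out = grid.cells[["mesh_id"]].copy()
    out["n_pixels"] = [counts.get(m, 0) for m in out["mesh_id"]]
    out["value"] = [sums[m] / counts[m] if counts.get(m) else np.nan
                    for m in out["mesh_id"]]
    out["missing"] = out["n_pixels"] == 0
    return out


# ---------------------------------------------------------------------------
# File I/O — single-band float32 GeoTIFF profile via tifffile


def save_raster(r: Raster, path) -> None:
    """Write a single-band float32 GeoTIFF (nodata encoded as NaN)."""
    values = r.values.astype(np.float32)
    values[r.nodata_mask] = np.nan
    cs = float(r.cell_size)
    ox, oy = r.origin
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_GDAL_NODATA, "s", 0, "nan"),
        # minimal GeoKey directory declaring a projected CRS in metres
        (_GEO_KEY_DIRECTORY, "H", 16,
         (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3076, 0, 1, 9001)),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


def load_raster(path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`save_raster` (or any
    north-up square-pixel float GeoTIFF with scale + tiepoint tags)."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            tags = page.tags
            values = page.asarray()
            has_georef = (_MODEL_PIXEL_SCALE in tags
                          and _MODEL_TIEPOINT in tags)
            if has_georef:
                sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
                tp = tags[_MODEL_TIEPOINT].value
            nodata_tag = (str(tags[_GDAL_NODATA].value)
                          if _GDAL_NODATA in tags else None)
    except (tifffile.TiffFileError, OSError) as exc:
        raise RasterFormatError(f"unreadable raster file: {path}") from exc
    if values.ndim != 2:
        raise RasterFormatError("only single-band rasters are supported")
    if not has_georef:
        raise RasterFormatError(f"file lacks georeferencing tags: {path}")
    if abs(sx - sy) > 1e-9:
        raise RasterFormatError("non-square pixels are not supported")
    # tiepoint maps raster (col, row) = (tp[0], tp[1]) to world (tp[3], tp[4])
    ox = float(tp[3]) - float(tp[0]) * sx
    oy = float(tp[4]) + float(tp[1]) * sy
    values = values.astype(float)
    mask = ~np.isfinite(values)
    if nodata_tag is not None:
        nd = nodata_tag.strip().strip("\x00")
        if nd and nd.lower() != "nan":
            mask |= values == float(nd)
    return Raster(values, float(sx), (ox, oy), mask)
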