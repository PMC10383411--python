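"""Spectral estimation of soil available nitrogen (SAN).

Bare-soil reflectance digital numbers (DN) in the green, red, Red edge and
NIR bands are summarised over buffer circles at the soil-sampling points,
expanded into a 28-variable feature inventory (4 single bands, 6 pairwise
differences, 6 sums, 6 ratios and 6 normalized difference indices
NDI(Ri, Rj) = (Ri − Rj)/(Ri + Rj)), and screened by single regression
against the measured chemistry.  The best-correlated feature — in the
reference field, the green − red difference — yields the SAN estimating
equation SAN = a + b * (green − red), which is then evaluated per pixel and
compiled onto the 1 m mesh as a soil fertility map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster_core import (BufferZone, EmptyZoneError, MeshGrid, Raster,
                          zonal_mean_circle, zonal_mean_mesh)

__all__ = [
    "BAND_NAMES",
    "OPTIMUM_SAN_RANGE",
    "FeatureSpec",
    "feature_inventory",
    "ScreeningResult",
    "LinearModel",
    "ndi",
    "ndvi_raster",
    "build_feature_table",
    "screen_features",
    "fit_san_model",
    "predict_san_raster",
    "fertility_mesh_map",
]

BAND_NAMES = ("green", "red", "red_edge", "nir")
_PAIRS = tuple(itertools.combinations(BAND_NAMES, 2))  # 6 ordered pairs

#: agronomic guidance: optimum soil available nitrogen, mg N kg^-1
OPTIMUM_SAN_RANGE = (80.0, 200.0)


@dataclass(frozen=True)
class FeatureSpec:
    """One explanatory variable of the screening inventory."""

    family: str                       # single | difference | sum | ratio | ndi
    band_i: str
    band_j: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("single", "difference", "sum", "ratio", "ndi"):
            raise ValueError(f"unknown feature family: {self.family}")
        if (self.family == "single") != (self.band_j is None):
            raise ValueError("band_j required iff the family is two-band")
        if self.band_j is not None and self.band_i == self.band_j:
            raise ValueError("two-band features need distinct bands")

    @property
    def name(self) -> str:
        if self.family == "single":
            return self.band_i
        symbol = {"difference": "-", "sum": "+", "ratio": "/"}.get(self.family)
        if symbol:
            return f"{self.band_i}{symbol}{self.band_j}"
        return f"ndi({self.band_i},{self.band_j})"

    def compute(self, bands: dict[str, np.ndarray] | pd.DataFrame):
        """Evaluate the feature from per-band values (scalars or arrays)."""
        a = np.asarray(bands[self.band_i], dtype=float)
        if self.family == "single":
            return a
        b = np.asarray(bands[self.band_j], dtype=float)
        if self.family == "difference":
            return a - b
        if self.family == "sum":
            return a + b
        if self.family == "ratio":
            return a / b
        return ndi(a, b)


def feature_inventory() -> list[FeatureSpec]:
    """The full 28-variable inventory: 4 singles + 6 each of difference,
    sum, ratio and NDI over the band pairs in canonical order."""
    inv = [FeatureSpec("single", b) for b in BAND_NAMES]
    for family in ("difference", "sum", "ratio", "ndi"):
        inv.extend(FeatureSpec(family, i, j) for i, j in _PAIRS)
    return inv


GREEN_MINUS_RED = FeatureSpec("difference", "green", "red")


def ndi(ri, rj):
    """Normalized difference index (Ri − Rj)/(Ri + Rj)."""
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    denom = ri + rj
    if np.any(denom == 0):
        raise ZeroDivisionError("NDI undefined where Ri + Rj = 0")
    out = (ri - rj) / denom
    return out if out.ndim else float(out)


def ndvi_raster(nir: Raster, red: Raster) -> Raster:
    """Per-pixel NDVI = NDI(NIR, red); nodata propagates."""
    if not nir.aligned_with(red):
        from .raster_core import AlignmentError
        raise AlignmentError("NIR and red rasters are not aligned")
    mask = nir.nodata_mask | red.nodata_mask
    denom = nir.values + red.values
    bad = mask | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (nir.values - red.values) / denom
    return Raster(np.where(bad, np.nan, vals), nir.cell_size, nir.origin, bad)


def build_feature_table(bands: dict[str, Raster], samples: pd.DataFrame,
                        radius: float = 0.5) -> pd.DataFrame:
    """One row per soil sample: buffer-mean DN per band plus all 28 features.

    ``samples`` needs columns ``id, x, y`` and any chemistry columns, which
    are carried through.  Raises :class:`EmptyZoneError` naming the sample
    if its buffer contains no valid pixels.
    """
    rows = []
    for rec in samples.itertuples(index=False):
        zone = BufferZone((rec.x, rec.y), radius)
        means = {}
        for name in BAND_NAMES:
            try:
                means[name], _ = zonal_mean_circle(bands[name], zone)
            except EmptyZoneError as exc:
                raise EmptyZoneError(
                    f"sample {rec.id}: empty {name}-band buffer at "
                    f"({rec.x:.2f}, {rec.y:.2f})") from exc
        rows.append(means)
    table = pd.concat([samples.reset_index(drop=True),
                       pd.DataFrame(rows).add_prefix("dn_")], axis=1)
    band_means = {b: table[f"dn_{b}"].to_numpy() for b in BAND_NAMES}
    for spec in feature_inventory():
        if spec.family == "single":
            continue  # identical to the dn_ column; keep one copy
        table[spec.name] = spec.compute(band_means)
    return table


@dataclass
class ScreeningResult:
    feature: FeatureSpec
    explained: str
    pearson_cc: float


def _feature_column(table: pd.DataFrame, spec: FeatureSpec) -> np.ndarray:
    col = f"dn_{spec.band_i}" if spec.family == "single" else spec.name
    return table[col].to_numpy(dtype=float)


def screen_features(table: pd.DataFrame, explained: str = "san"
                    ) -> list[ScreeningResult]:
    """Pearson correlation of every inventory feature with one chemistry
    variable, sorted by |cc| descending (ties keep inventory order).

    Constant features get a NaN coefficient rather than being dropped.
    """
    y = table[explained].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("screening needs at least 3 samples")
    if np.std(y) == 0:
        raise ValueError(f"explained variable {explained!r} is constant")
    results = []
    for spec in feature_inventory():
        x = _feature_column(table, spec)
        cc = (float(stats.pearsonr(x, y).statistic)
              if np.std(x) > 0 else float("nan"))
        results.append(ScreeningResult(spec, explained, cc))
    return sorted(results,
                  key=lambda r: -abs(r.pearson_cc) if np.isfinite(r.pearson_cc)
                  else np.inf)


def screening_table(table: pd.DataFrame,
                    explained_vars: tuple[str, ...] = ("tn", "tc", "san")
                    ) -> pd.DataFrame:
    """Inventory-ordered correlation matrix, one column per chemistry variable."""
    out = pd.DataFrame({"feature": [s.name for s in feature_inventory()],
                        "family": [s.family for s in feature_inventory()]})
    for var in explained_vars:
        by_name = {r.feature.name: r.pearson_cc
                   for r in screen_features(table, var)}
        out[var] = [by_name[f] for f in out["feature"]]
    return out


@dataclass
class LinearModel:
    """Single-regression SAN estimating equation SAN = intercept + slope*x."""

    intercept: float
    slope: float
    r_squared: float
    aic: float
    n: int
    feature: FeatureSpec

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_san_model(table: pd.DataFrame, feature: FeatureSpec = GREEN_MINUS_RED,
                  explained: str = "san") -> LinearModel:
    """Ordinary least squares of the chemistry variable on one feature.

    AIC uses the Gaussian profile form n*ln(RSS/n) + 2k with k = 2
    (constants dropped; only differences between fits are meaningful).
    """
    x = _feature_column(table, feature)
    y = table[explained].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("fit needs at least 3 samples")
    if np.std(x) == 0:
        raise ValueError(f"feature {feature.name!r} has zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rss = float(resid @ resid)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 2
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0  # constant y
    return LinearModel(intercept=float(fit.intercept), slope=float(fit.slope),
                       r_squared=r2, aic=float(aic), n=n, feature=feature)


def predict_san_raster(model: LinearModel, bands: dict[str, Raster],
                       clip_range: tuple[float, float] | None = None) -> Raster:
    """Evaluate the estimating equation per pixel.

    Prediction uses raw pixel DN (the fitted buffer means only enter the
    regression); optional clipping to a plausibility range is off by default.
    """
    spec = model.feature
    needed = [spec.band_i] + ([spec.band_j] if spec.band_j else [])
    for b in needed:
        if b not in bands:
            raise KeyError(f"missing band raster: {b}")
    ref = bands[needed[0]]
    mask = np.zeros(ref.shape, dtype=bool)
    for b in needed:
        mask |= bands[b].nodata_mask
    x = spec.compute({b: bands[b].values for b in needed})
    vals = model.predict(x)
    if clip_range is not None:
        vals = np.clip(vals, *clip_range)
    return Raster(np.where(mask, np.nan, vals), ref.cell_size, ref.origin, mask)


def fertility_mesh_map(san: Raster, grid: MeshGrid,
                       optimum: tuple[float, float] = OPTIMUM_SAN_RANGE
                       ) -> pd.DataFrame:
    """Mesh-cell mean SAN with an optimum-range flag per cell.

    Columns: ``mesh_id, x, y, san_est, n_pixels, missing, in_optimum``.
    """
    z = zonal_mean_mesh(san, grid).rename(columns={"value": "san_est"})
    out = grid.cells[["mesh_id", "x", "y", "is_edge"]].merge(z, on="mesh_id")
    lo, hi = optimum
    out["in_optimum"] = (out["san_est"] >= lo) & (out["san_est"] <= hi)
    return out[["mesh_id", "x", "y", "is_edge", "san_est", "n_pixels",
                "missing", "in_optimum"]]
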