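"""Synthetic paddy-field generator.

Produces the full set of survey artefacts the downstream analysis consumes —
bare-soil terrain model, canopy-maximum and harvest surface models, four
reflectance-scaled band rasters, a soil-sample point table and the field
boundary — with the statistical structure the analysis assumes:

* a smooth, spatially correlated available-nitrogen (SAN) surface in
  78–200 mg N kg^-1 with a north-to-south decreasing trend;
* a green−red digital-number difference linearly tied to SAN
  (green − red = (287.86 − SAN) / 0.046 plus noise), so the nitrogen
  estimating equation is recoverable from the bands;
* a bare-soil "soil line" in red–NIR space, with a configurable fraction
  of vegetation-residue mixels sitting above it;
* canopy heights whose collapse between seasonal maximum and harvest
  increases with SAN above a lodging-onset concentration, with the outer
  edge strip lodging regardless of SAN (fertilizer-overlap artefact).

Everything is deterministic under ``FieldConfig.seed``; each generator
draws from its own seed-derived stream so operations can be called in any
order.  The synthetic inclination-angle response to SAN (upright at or
below the onset, linearly falling to ``theta_floor_deg`` at the SAN
maximum) is a stand-in: no quantitative lodging response curve is claimed
for real fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster_core import FieldBoundary, Raster

__all__ = [
    "FieldConfig",
    "SyntheticField",
    "generate_san_field",
    "generate_dtm",
    "render_bands",
    "render_canopy",
    "sample_points",
    "simulate_field",
]

# Coefficients of the nitrogen estimating equation SAN = a + b * (green - red);
# the band generator inverts this relation.
SAN_INTERCEPT = 287.86
SAN_SLOPE = -0.046

BAND_NAMES = ("green", "red", "red_edge", "nir")


@dataclass
class FieldConfig:
    """Generating conditions for one synthetic paddy field.

    Defaults reproduce the reference scenario: a 55 x 80 m field,
    ~5 cm ground sample distance, SAN spanning 78–200 mg N kg^-1,
    a 0.15 deg terrain slope, 20 + 15 soil samples and a one-shot basal
    dressing of 70 kg N ha^-1.
    """

    width: float = 55.0              # m, east-west extent
    height: float = 80.0             # m, north-south extent
    band_cell_size: float = 0.051    # m, multispectral GSD
    elevation_cell_size: float = 0.05  # m, DSM/DTM GSD
    base_elevation: float = 4.7      # m, mean ground elevation
    slope_deg: float = 0.15          # deg, terrain tilt (down toward south)
    san_range: tuple[float, float] = (78.0, 200.0)  # mg N kg^-1
    san_correlation_length: float = 12.0  # m, patch scale of the SAN field
    noise_sd_san: float = 8.0        # mg N kg^-1, soil-measurement noise
    noise_sd_band: float = 50.0      # DN, per-band sensor/surface noise
    noise_sd_height: float = 0.03    # m, photogrammetric height noise
    residue_fraction: float = 0.2    # proportion of mixel pixels
    n_samples_a: int = 20
    n_samples_b: int = 15
    fertilizer_n: float = 70.0       # kg N ha^-1
    lodging_onset_san: float = 140.0  # mg N kg^-1, upright below this
    theta_floor_deg: float = 10.0    # deg, inclination at the SAN maximum
    canopy_height_range: tuple[float, float] = (0.5, 0.7)  # m, max CHM span
    edge_lodge_width: float = 4.0    # m, strip that lodges regardless of SAN
    red_base_dn: float = 1500.0      # DN, mean bare-soil red reflectance
    red_spatial_sd: float = 300.0    # DN, SAN-independent brightness patches
    red_edge_spatial_sd: float = 400.0  # DN, Red-edge-specific soil variation
    soil_line_intercept: float = 150.0  # DN, NIR at red = 0 on the soil line
    soil_line_slope: float = 1.3     # DN/DN, soil-line gradient
    mixel_nir_boost: float = 700.0   # DN, NIR uplift of residue mixels
    mixel_patch_length: float = 4.0  # m, clustering scale of residue patches
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.san_range
        if not (0 < lo < hi < 500):
            raise ValueError("san_range must satisfy 0 < min < max < 500")
        if not 0 <= self.residue_fraction <= 1:
            raise ValueError("residue_fraction must lie in [0, 1]")
        if self.n_samples_a < 1 or self.n_samples_b < 1:
            raise ValueError("sample counts must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator component."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def boundary(self) -> FieldBoundary:
        return FieldBoundary.rectangle(self.width, self.height)

    def _grid(self, cell_size: float) -> tuple[int, int, tuple[float, float]]:
        n_cols = int(round(self.width / cell_size))
        n_rows = int(round(self.height / cell_size))
        # origin at the field's north-west corner (top-left)
        return n_rows, n_cols, (0.0, self.height)


@dataclass
class SyntheticField:
    """Bundle of all generated artefacts plus the latent truth."""

    config: FieldConfig
    boundary: FieldBoundary
    dtm: Raster
    dsm_max: Raster
    dsm_harvest: Raster
    bands: dict[str, Raster]
    samples: pd.DataFrame
    san_truth: Raster           # latent SAN on the band grid
    mixel_mask: np.ndarray      # which band pixels carry residue


def _correlated_field(shape: tuple[int, int], cell_size: float,
                      correlation_length: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth noise via moving-average smoothing of white noise.

    A correlation length of zero (or below one pixel) returns the white
    field unchanged.
    """
    white = rng.standard_normal(shape)
    k = int(round(correlation_length / cell_size))
    if k <= 1:
        return white
    smooth = ndimage.uniform_filter(white, size=k, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_san_field(cfg: FieldConfig) -> Raster:
    """Latent SAN surface on the band grid, clipped to ``cfg.san_range``.

    Built as a north→south decreasing linear trend plus smoothed Gaussian
    noise, so the high-nitrogen (lodging-prone) ground sits on the north
    side of the field.
    """
    n_rows, n_cols, origin = cfg._grid(cfg.band_cell_size)
    lo, hi = cfg.san_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    # row 0 is north; trend runs from +0.75*half at north to -0.75*half at south
    northness = 1.0 - 2.0 * (np.arange(n_rows) + 0.5) / n_rows
    trend = mid + 0.75 * half * northness[:, None]
    noise = _correlated_field((n_rows, n_cols), cfg.band_cell_size,
                              cfg.san_correlation_length, cfg.rng(1))
    values = np.clip(trend + 0.45 * half * noise, lo, hi)
    return Raster(values, cfg.band_cell_size, origin)


def generate_dtm(cfg: FieldConfig) -> Raster:
    """Bare-soil terrain model: a gently tilted plane plus smooth microrelief."""
    n_rows, n_cols, origin = cfg._grid(cfg.elevation_cell_size)
    ys = (np.arange(n_rows) + 0.5) * cfg.elevation_cell_size  # distance from north
    tilt = np.tan(np.radians(cfg.slope_deg))
    plane = cfg.base_elevation + tilt * (cfg.height / 2.0 - ys)[:, None]
    micro = 0.005 * _correlated_field((n_rows, n_cols), cfg.elevation_cell_size,
                                      5.0, cfg.rng(2))
    # detrend the microrelief so the field's plane-fit slope stays exactly
    # at slope_deg regardless of the random draw
    xs = (np.arange(n_cols) + 0.5) * cfg.elevation_cell_size
    design = np.column_stack([np.ones(micro.size),
                              np.broadcast_to(xs, micro.shape).ravel(),
                              np.broadcast_to(ys[:, None], micro.shape).ravel()])
    coef, *_ = np.linalg.lstsq(design, micro.ravel(), rcond=None)
    micro = micro - (design @ coef).reshape(micro.shape)
    return Raster(np.broadcast_to(plane, (n_rows, n_cols)) + micro,
                  cfg.elevation_cell_size, origin)


def _resample_nearest(src: Raster, template: Raster) -> np.ndarray:
    """Sample ``src`` at the pixel centres of ``template`` (nearest cell)."""
    px, py = template.pixel_centres()
    row, col = src.index_of(px, py)
    row = np.clip(row, 0, src.shape[0] - 1)
    col = np.clip(col, 0, src.shape[1] - 1)
    return src.values[row, col]


def synthetic_theta(san: np.ndarray, cfg: FieldConfig) -> np.ndarray:
    """Noise-free inclination response: 90 deg at or below the lodging onset,
    linear decrease to ``theta_floor_deg`` at the SAN range maximum."""
    onset = cfg.lodging_onset_san
    hi = cfg.san_range[1]
    frac = np.clip((san - onset) / (hi - onset), 0.0, 1.0)
    return 90.0 - (90.0 - cfg.theta_floor_deg) * frac


def render_canopy(san: Raster, cfg: FieldConfig,
                  dtm: Raster | None = None) -> tuple[Raster, Raster]:
    """Surface models at canopy maximum and at harvest on the elevation grid.

    Maximum canopy height r sits in ``canopy_height_range`` and grows weakly
    with SAN; harvest height is y = r*sin(theta) with theta from
    :func:`synthetic_theta`, forced low in the outer edge strip.
    """
    if dtm is None:
        dtm = generate_dtm(cfg)
    san_e = _resample_nearest(san, dtm)
    lo, hi = cfg.san_range
    r_lo, r_hi = cfg.canopy_height_range
    rng = cfg.rng(3)
    r = r_lo + (r_hi - r_lo) * (san_e - lo) / (hi - lo)
    theta = synthetic_theta(san_e, cfg)

    if cfg.edge_lodge_width > 0:  # headland strip lodges irrespective of SAN
        px, py = dtm.pixel_centres()
        d_edge = np.minimum.reduce([px, cfg.width - px, py, cfg.height - py])
        theta = np.where(d_edge < cfg.edge_lodge_width,
                         np.minimum(theta, 15.0), theta)

    y = r * np.sin(np.radians(theta))
    noise = cfg.noise_sd_height
    dsm_max = dtm.values + r + noise * rng.standard_normal(dtm.shape)
    dsm_harvest = dtm.values + y + noise * rng.standard_normal(dtm.shape)
    return (Raster(dsm_max, dtm.cell_size, dtm.origin),
            Raster(dsm_harvest, dtm.cell_size, dtm.origin))


def render_bands(san: Raster, cfg: FieldConfig
                 ) -> tuple[dict[str, Raster], np.ndarray]:
    """Four bare-soil band rasters consistent with the SAN surface.

    green − red inverts the nitrogen estimating equation; red and NIR lie on
    the linear soil line for clean pixels while a ``residue_fraction`` of
    mixels get an elevated NIR; Red edge is interpolated midway between red
    and NIR.  Returns the band dict and the boolean mixel mask.
    """
    rng = cfg.rng(4)
    shape = san.shape
    sd = cfg.noise_sd_band

    # soil brightness varies independently of SAN (moisture/texture patches);
    # the variation cancels exactly in green - red but degrades every other
    # two-band combination, mirroring why that index screens best.
    red = (cfg.red_base_dn
           + cfg.red_spatial_sd * _correlated_field(shape, san.cell_size,
                                                    8.0, rng)
           + sd * rng.standard_normal(shape))
    gr_diff = (SAN_INTERCEPT - san.values) / (-SAN_SLOPE)
    green = red + gr_diff + sd * rng.standard_normal(shape)
    nir = (cfg.soil_line_intercept + cfg.soil_line_slope * red
           + 0.6 * sd * rng.standard_normal(shape))
    # residue lies in patches (tillage rows), not as independent pixels:
    # threshold a smooth field so exactly residue_fraction of pixels are mixels
    if cfg.residue_fraction > 0:
        patchiness = _correlated_field(shape, san.cell_size,
                                       cfg.mixel_patch_length, rng)
        cut = np.quantile(patchiness, 1.0 - cfg.residue_fraction)
        mixels = patchiness > cut
    else:
        mixels = np.zeros(shape, dtype=bool)
    nir = nir + mixels * (cfg.mixel_nir_boost
                          + 0.2 * cfg.mixel_nir_boost * rng.standard_normal(shape))
    red_edge = (0.5 * (red + nir)
                + cfg.red_edge_spatial_sd * _correlated_field(
                    shape, san.cell_size, 8.0, rng)
                + sd * rng.standard_normal(shape))

    bands = {name: Raster(arr, san.cell_size, san.origin)
             for name, arr in zip(BAND_NAMES, (green, red, red_edge, nir))}
    return bands, mixels


def sample_points(san: Raster, cfg: FieldConfig) -> pd.DataFrame:
    """Soil-sample table: jittered-grid points with measured chemistry.

    Measured SAN is the latent surface value plus Gaussian noise
    (``noise_sd_san``); total carbon and nitrogen are generated with only a
    weak correlation to SAN, mimicking chemistry panels where SAN is the
    informative variable.
    """
    n = cfg.n_samples_a + cfg.n_samples_b
    rng = cfg.rng(5)
    # jittered grid: near-square layout covering the field interior
    n_x = int(np.ceil(np.sqrt(n * cfg.width / cfg.height)))
    n_y = int(np.ceil(n / n_x))
    if n_x * n_y < n:
        raise ValueError("cannot place the requested number of samples")
    margin = 2.0
    gx = margin + (cfg.width - 2 * margin) * (np.arange(n_x) + 0.5) / n_x
    gy = margin + (cfg.height - 2 * margin) * (np.arange(n_y) + 0.5) / n_y
    xs, ys = np.meshgrid(gx, gy)
    pts = np.column_stack([xs.ravel(), ys.ravel()])[:n]
    jitter_x = (cfg.width - 2 * margin) / n_x * 0.3
    jitter_y = (cfg.height - 2 * margin) / n_y * 0.3
    pts[:, 0] += rng.uniform(-jitter_x, jitter_x, n)
    pts[:, 1] += rng.uniform(-jitter_y, jitter_y, n)

    row, col = san.index_of(pts[:, 0], pts[:, 1])
    latent = san.values[np.clip(row, 0, san.shape[0] - 1),
                        np.clip(col, 0, san.shape[1] - 1)]
    measured = latent + cfg.noise_sd_san * rng.standard_normal(n)

    z = (measured - measured.mean()) / max(measured.std(), 1e-9)
    tc = 2.0 + 0.2 * (0.4 * z + np.sqrt(1 - 0.4**2) * rng.standard_normal(n))
    tn = tc / 12.0 + 0.01 * rng.standard_normal(n)
    return pd.DataFrame({
        "id": np.arange(n),
        "x": pts[:, 0], "y": pts[:, 1],
        "san": measured, "tc": tc, "tn": tn,
        "latent_san": latent,
    })


def simulate_field(cfg: FieldConfig | None = None) -> SyntheticField:
    """Generate the complete reference field for a configuration."""
    cfg = cfg or FieldConfig()
    san = generate_san_field(cfg)
    dtm = generate_dtm(cfg)
    dsm_max, dsm_harvest = render_canopy(san, cfg, dtm)
    bands, mixels = render_bands(san, cfg)
    samples = sample_points(san, cfg)
    return SyntheticField(config=cfg, boundary=cfg.boundary(), dtm=dtm,
                          dsm_max=dsm_max, dsm_harvest=dsm_harvest,
                          bands=bands, samples=samples, san_truth=san,
                          mixel_mask=mixels)


def config_to_dict(cfg: FieldConfig) -> dict:
    return asdict(cfg)
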