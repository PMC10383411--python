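"""End-to-end pipeline: synthetic survey → lodging map → fertility map → risk.

Used by the ``full-run`` CLI subcommand and importable directly.  All stages
are deterministic given the field configuration's seed; rerunning with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import lodging as lodge
from . import risk_analysis as risk_mod
from . import soil_line as sl
from . import soil_spectral as ss
from .raster_core import make_mesh_grid, save_raster
from .synthetic_data import BAND_NAMES, FieldConfig, simulate_field


def run_pipeline(cfg: FieldConfig, out_dir: Path | None = None, *,
                 cell_size: float = 1.0, edge_width: float = 4.0,
                 radius: float = 0.5, thresholds: dict | None = None,
                 soilline_subsample: int = 20000) -> dict:
    """Run every stage on a synthetic field and return the summary report.

    When ``out_dir`` is given, intermediate rasters and mesh CSVs are
    written there as a side effect.
    """
    thresholds = thresholds or {}
    onset = float(thresholds.get("onset", risk_mod.DEFAULT_ONSET_SAN))
    guideline = float(thresholds.get("guideline", risk_mod.DEFAULT_GUIDELINE))

    field = simulate_field(cfg)
    grid = make_mesh_grid(field.boundary, cell_size, edge_width)

    # lodging assessment
    r_chm = lodge.compute_chm(field.dsm_max, field.dtm)
    y_chm = lodge.compute_chm(field.dsm_harvest, field.dtm)
    delta = lodge.delta_chm(r_chm, y_chm)
    theta = lodge.inclination_angle(r_chm, y_chm)
    lodging_mesh = lodge.lodging_mesh_map(theta, delta, grid)

    # soil fertility assessment
    table = ss.build_feature_table(field.bands, field.samples, radius)
    ranked = ss.screen_features(table, "san")
    model = ss.fit_san_model(table, ranked[0].feature, "san")
    san_raster = ss.predict_san_raster(model, field.bands)
    fertility_mesh = ss.fertility_mesh_map(san_raster, grid)

    # soil-line classification on a deterministic pixel subsample
    stack = np.column_stack([field.bands[b].values.ravel()
                             for b in BAND_NAMES])
    if len(stack) > soilline_subsample:
        idx = cfg.rng(6).choice(len(stack), soilline_subsample, replace=False)
        stack = stack[idx]
    soilline = sl.estimate_mixel_fraction(stack)

    # risk synthesis
    joined = risk_mod.join_mesh(lodging_mesh, fertility_mesh)
    corr = risk_mod.correlate_inside(joined)
    fert = risk_mod.fertilizer_to_soil_n(cfg.fertilizer_n)
    risk = risk_mod.risk_map(joined, fert, onset, guideline)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_raster(theta, out / "theta.tif")
        save_raster(delta, out / "delta_chm.tif")
        save_raster(san_raster, out / "san.tif")
        lodging_mesh.to_csv(out / "lodging_mesh.csv", index=False)
        fertility_mesh.to_csv(out / "fertility_mesh.csv", index=False)
        risk.to_csv(out / "risk_mesh.csv", index=False)
        field.samples.to_csv(out / "samples.csv", index=False)

    line = soilline["soil_line"]
    return {
        "seed": cfg.seed,
        "n_samples": int(len(field.samples)),
        "best_feature": ranked[0].feature.name,
        "best_feature_cc": float(ranked[0].pearson_cc),
        "san_model": {"intercept": model.intercept, "slope": model.slope,
                      "r_squared": model.r_squared, "aic": model.aic},
        "mesh": {"n_total": corr.n_total, "n_inside": corr.n_inside,
                 "n_edge": corr.n_edge,
                 "inside_fraction": corr.inside_fraction},
        "correlation": {"pearson_r_inside": corr.pearson_r_inside,
                        "theta_on_san_slope": corr.slope,
                        "theta_on_san_intercept": corr.intercept},
        "fertilizer_mg_per_kg": fert,
        "soil_line": None if line is None else
            {"intercept": line.intercept, "slope": line.slope,
             "rmse": line.rmse},
        "mixel_fraction": soilline["mixel_fraction"],
        "risk_counts": {
            "lodging_possible": int(risk["lodging_possible"].sum()),
            "above_guideline": int(risk["above_guideline"].sum()),
            "edge_caution": int(risk["edge_caution"].sum()),
            "ok": int((risk["risk_flag"] == "ok").sum()),
        },
    }
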