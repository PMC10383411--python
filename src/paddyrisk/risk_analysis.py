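"""Lodging-risk synthesis on the 1 m mesh.

Joins the lodging and soil-fertility mesh tables, quantifies the
inside-field relationship between estimated soil available nitrogen (SAN)
and the rice inclination angle, converts the basal fertilizer dressing to a
soil concentration, and flags each cell by absorbable nitrogen
(SAN + fertilizer N) against the lodging-onset and guideline thresholds.

Edge cells — the outer strip where the transplanter's overlapping fertilizer
application lodges rice regardless of soil nitrogen — are excluded from the
correlation and carry a separate caution flag that is never merged into the
SAN-based risk flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "join_mesh",
    "correlate_inside",
    "fertilizer_to_soil_n",
    "absorbable_n",
    "risk_map",
    "DEFAULT_ONSET_SAN",
    "DEFAULT_GUIDELINE",
]

#: SAN at and above which lodging was possible, mg N kg^-1
DEFAULT_ONSET_SAN = 140.0
#: desirable upper bound on absorbable nitrogen, mg N kg^-1
DEFAULT_GUIDELINE = 200.0


@dataclass
class CorrelationReport:
    """Inside-mesh SAN–inclination correlation summary."""

    n_total: int
    n_inside: int
    n_edge: int
    pearson_r_inside: float
    intercept: float     # theta (deg) at SAN = 0 of the fitted line
    slope: float         # deg per mg N kg^-1

    @property
    def inside_fraction(self) -> float:
        return self.n_inside / self.n_total if self.n_total else float("nan")


def join_mesh(lodging: pd.DataFrame, fertility: pd.DataFrame) -> pd.DataFrame:
    """Inner join of the two mesh tables on ``mesh_id``.

    Cells missing either value (flagged missing or NaN) are dropped; the
    drop count is recorded in ``DataFrame.attrs['n_dropped']``.  Disjoint
    grids raise a ``ValueError``.
    """
    lhs = lodging.loc[~lodging["missing"].astype(bool)] \
        if "missing" in lodging else lodging
    rhs = fertility.loc[~fertility["missing"].astype(bool)] \
        if "missing" in fertility else fertility
    rhs_cols = ["mesh_id", "san_est"] + (
        ["in_optimum"] if "in_optimum" in rhs else [])
    joined = lhs.merge(rhs[rhs_cols], on="mesh_id", how="inner")
    joined = joined.dropna(subset=["san_est", "theta"]).reset_index(drop=True)
    if joined.empty:
        raise ValueError("mesh tables share no cells: disjoint grids?")
    joined.attrs["n_dropped"] = max(len(lodging), len(fertility)) - len(joined)
    return joined


def correlate_inside(joined: pd.DataFrame) -> CorrelationReport:
    """Pearson r and OLS line of theta on SAN over inside (non-edge) cells.

    Edge cells are counted but excluded from the statistics.
    """
    edge = joined["is_edge"].astype(bool)
    inside = joined.loc[~edge]
    if len(inside) < 3:
        raise ValueError("need at least 3 inside cells")
    san = inside["san_est"].to_numpy(dtype=float)
    theta = inside["theta"].to_numpy(dtype=float)
    if np.std(san) == 0 or np.std(theta) == 0:
        raise ValueError("correlation undefined: a variable is constant")
    fit = stats.linregress(san, theta)
    return CorrelationReport(
        n_total=len(joined), n_inside=len(inside), n_edge=int(edge.sum()),
        pearson_r_inside=float(fit.rvalue),
        intercept=float(fit.intercept), slope=float(fit.slope))


def fertilizer_to_soil_n(rate: float, depth: float = 0.1,
                         bulk_density: float = 1.0) -> float:
    """Convert a dressing rate (kg N ha^-1) to a soil concentration
    (mg N kg^-1) mixed through the tillage layer.

    One hectare of soil to ``depth`` m at ``bulk_density`` Mg m^-3 weighs
    10^4 * depth * bulk_density Mg, so the concentration is
    rate / (10 * depth * bulk_density).  The reference dressing of
    70 kg N ha^-1 over 0.1 m at 1.0 Mg m^-3 gives 70 mg N kg^-1.
    """
    if rate < 0:
        raise ValueError("fertilizer rate must be non-negative")
    if depth <= 0 or bulk_density <= 0:
        raise ValueError("depth and bulk density must be positive")
    return rate / (10.0 * depth * bulk_density)


def absorbable_n(san_est, fert):
    """Absorbable nitrogen: soil available N plus fertilizer-derived N,
    both in mg N kg^-1."""
    san_est = np.asarray(san_est, dtype=float)
    if np.any(san_est < 0) or np.any(np.asarray(fert) < 0):
        raise ValueError("nitrogen amounts must be non-negative")
    out = san_est + fert
    return out if out.ndim else float(out)


def risk_map(joined: pd.DataFrame, fert: float,
             onset: float = DEFAULT_ONSET_SAN,
             guideline: float = DEFAULT_GUIDELINE) -> pd.DataFrame:
    """Per-cell absorbable nitrogen and risk flags.

    ``lodging_possible`` where estimated SAN >= onset; ``above_guideline``
    where absorbable N >= guideline; ``edge_caution`` on edge cells (the
    fertilizer-overlap strip lodges regardless of SAN); ``risk_flag``
    summarises the SAN-based flags only.
    """
    if onset <= 0 or guideline <= 0:
        raise ValueError("thresholds must be positive")
    out = joined.copy()
    san = out["san_est"].to_numpy(dtype=float)
    out["absorbable_n"] = absorbable_n(np.maximum(san, 0.0), fert)
    out["lodging_possible"] = san >= onset
    out["above_guideline"] = out["absorbable_n"] >= guideline
    out["edge_caution"] = out["is_edge"].astype(bool)
    flags = np.where(out["above_guideline"], "above_guideline", "ok")
    flags = np.where(out["lodging_possible"] & out["above_guideline"],
                     "lodging_possible+above_guideline", flags)
    flags = np.where(out["lodging_possible"] & ~out["above_guideline"],
                     "lodging_possible", flags)
    out["risk_flag"] = flags
    return out
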