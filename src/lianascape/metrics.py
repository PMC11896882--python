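"""Quadrat-level liana-structure and environmental variables.

Liana structure (per 20 x 20 m quadrat):

* ``N_L``   liana abundance, stems/ha
* ``BA_L``  liana total basal area, m^2/ha
* ``QMD_L`` liana quadratic mean diameter, cm

Environment (per quadrat, tree and canopy variables over the buffered
40 x 40 m window):

* ``N_T``, ``BA_T``, ``QMD_T`` as above for trees (>= 10 cm DBH)
* ``WD_T``  mean wood density over stems, g/cm^3 (unweighted by default)
* ``dBA_T`` basal-area change between the two censuses, absolute m^2
* ``meanTCH`` mean top-of-canopy height (DSM - DEM), m
* ``GHFC``  giant-herb foliar cover index, mean of the 9 grid points in the
  quadrat (10-m lattice, closed bounds)
* ``RSP``   mean relative slope position over the window, dimensionless
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Raster
from .terrain import relative_slope_position

__all__ = [
    "stem_basal_area",
    "quadrat_liana_structure",
    "window_tree_metrics",
    "mean_tch",
    "giant_herb_cover",
    "rsp_table",
    "standardize",
    "correlation_screen",
    "env_table",
    "ENV_COLUMNS",
]

ENV_COLUMNS = ["N_T", "BA_T", "QMD_T", "WD_T", "dBA_T", "meanTCH", "GHFC", "RSP"]


def stem_basal_area(d: float | np.ndarray) -> float | np.ndarray:
    """Cross-sectional area in m^2 of a stem of diameter ``d`` cm."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("stem diameter must be > 0 cm")
    out = np.pi * (d / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


def _qmd(d: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(d)))) if d.size else float("nan")


def quadrat_liana_structure(lianas: pd.DataFrame, quadrats: pd.DataFrame) -> pd.DataFrame:
    """Per-quadrat N_L (stems/ha), BA_L (m^2/ha) and QMD_L (cm).

    Empty quadrats get N_L = BA_L = 0 and QMD_L = NaN (flagged missing).
    """
    area_ha = (quadrats["side"] ** 2 / 10_000.0).to_numpy()
    rows = []
    grouped = dict(tuple(lianas.groupby("quadrat_id")))
    for (_, q), a in zip(quadrats.iterrows(), area_ha):
        sub = grouped.get(q["quadrat_id"])
        d = sub["diameter"].to_numpy() if sub is not None else np.empty(0)
        rows.append({
            "quadrat_id": q["quadrat_id"],
            "N_L": d.size / a,
            "BA_L": float(np.sum(stem_basal_area(d))) / a if d.size else 0.0,
            "QMD_L": _qmd(d),
        })
    return pd.DataFrame(rows).set_index("quadrat_id")


def window_tree_metrics(trees: pd.DataFrame, quadrats: pd.DataFrame) -> pd.DataFrame:
    """Tree variables over each quadrat's buffered 40 x 40 m window.

    N_T, BA_T and QMD_T use the later census (stems alive then); dBA_T is the
    absolute basal-area change (m^2, not per ha) between the two censuses.
    WD_T is the unweighted mean wood density over live stems.
    """
    rows = []
    for plot_id, qsub in quadrats.groupby("plot_id", sort=False):
        t = trees[trees["plot_id"] == plot_id]
        x, y = t["x"].to_numpy(), t["y"].to_numpy()
        d1 = t["dbh_census1"].to_numpy(dtype=float)
        d2 = t["dbh_census2"].to_numpy(dtype=float)
        wd = t["wood_density"].to_numpy(dtype=float)
        for _, q in qsub.iterrows():
            x0, y0, side = q["bx0"], q["by0"], q["bside"]
            inw = (x >= x0) & (x < x0 + side) & (y >= y0) & (y < y0 + side)
            area_ha = side * side / 10_000.0
            w2 = inw & ~np.isnan(d2)
            w1 = inw & ~np.isnan(d1)
            dd = d2[w2]
            ba2 = float(np.sum(stem_basal_area(dd))) if dd.size else 0.0
            ba1 = float(np.sum(stem_basal_area(d1[w1]))) if w1.any() else 0.0
            rows.append({
                "quadrat_id": q["quadrat_id"],
                "N_T": dd.size / area_ha,
                "BA_T": ba2 / area_ha,
                "QMD_T": _qmd(dd),
                "WD_T": float(np.mean(wd[w2])) if dd.size else float("nan"),
                "dBA_T": ba2 - ba1,
            })
    out = pd.DataFrame(rows).set_index("quadrat_id")
    return out.reindex(quadrats["quadrat_id"])


def mean_tch(dsm: Raster, dem: Raster, quadrats: pd.DataFrame,
             plot_id: str | None = None) -> pd.Series:
    """Mean canopy height (DSM - DEM, clipped at 0) over buffered windows.

    Rasters are plot-local; pass ``plot_id`` to restrict the quadrat frame,
    or leave None when the frame already belongs to a single plot.
    """
    if (dsm.cell_size != dem.cell_size or dsm.values.shape != dem.values.shape
            or dsm.x0 != dem.x0 or dsm.y0 != dem.y0):
        raise ValueError("DSM and DEM rasters are not aligned")
    chm = np.clip(dsm.values - dem.values, 0.0, None)
    chm_r = Raster(dsm.x0, dsm.y0, dsm.cell_size, chm, nodata=dsm.nodata)
    nod = (dsm.values == dsm.nodata) | (dem.values == dem.nodata)
    chm_r.values[nod] = chm_r.nodata
    qsub = quadrats if plot_id is None else quadrats[quadrats["plot_id"] == plot_id]
    out = {}
    for _, q in qsub.iterrows():
        vals = chm_r.window_values(q["bx0"], q["by0"], q["bx0"] + q["bside"], q["by0"] + q["bside"])
        if vals.size == 0:
            raise ValueError(f"quadrat {q['quadrat_id']}: fully-nodata canopy window")
        out[q["quadrat_id"]] = float(vals.mean())
    return pd.Series(out, name="meanTCH")


def giant_herb_cover(herbs: pd.DataFrame, quadrats: pd.DataFrame,
                     expected_points: int = 9) -> pd.DataFrame:
    """GHFC: mean cover index of the herb grid points inside each quadrat.

    Bounds are closed on both sides so a 20 x 20 m quadrat aligned on the
    10-m herb lattice contains a 3 x 3 block of points.  Quadrats with fewer
    than ``expected_points`` points are flagged (``n_points`` column).
    """
    rows = []
    for plot_id, qsub in quadrats.groupby("plot_id", sort=False):
        h = herbs[herbs["plot_id"] == plot_id]
        x, y = h["x"].to_numpy(), h["y"].to_numpy()
        v = h["cover_index"].to_numpy(dtype=float)
        eps = 1e-9
        for _, q in qsub.iterrows():
            sel = ((x >= q["x0"] - eps) & (x <= q["x0"] + q["side"] + eps)
                   & (y >= q["y0"] - eps) & (y <= q["y0"] + q["side"] + eps))
            n = int(sel.sum())
            rows.append({
                "quadrat_id": q["quadrat_id"],
                "GHFC": float(v[sel].mean()) if n else float("nan"),
                "n_points": n,
            })
    out = pd.DataFrame(rows).set_index("quadrat_id").reindex(quadrats["quadrat_id"])
    out["complete"] = out["n_points"] >= expected_points
    return out


def rsp_table(dem: Raster, quadrats: pd.DataFrame, plot_id: str | None = None,
              threshold_cells: float | None = None) -> pd.Series:
    """Mean RSP over each quadrat's buffered window (plot-local raster)."""
    rsp = relative_slope_position(dem, threshold_cells)
    r = Raster(dem.x0, dem.y0, dem.cell_size, rsp, nodata=-9999.0)
    qsub = quadrats if plot_id is None else quadrats[quadrats["plot_id"] == plot_id]
    out = {}
    for _, q in qsub.iterrows():
        vals = r.window_values(q["bx0"], q["by0"], q["bx0"] + q["bside"], q["by0"] + q["bside"])
        out[q["quadrat_id"]] = float(vals.mean())
    return pd.Series(out, name="RSP")


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sd 1 (ddof=1)."""
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (df - df.mean()) / sd


def correlation_screen(env: pd.DataFrame, cutoff: float = 0.7) -> pd.DataFrame:
    """Pairwise |Pearson r| among predictors; rows with ``flag`` where >= cutoff."""
    if (env.std(ddof=1) == 0).any():
        raise ValueError("constant column in environment table")
    corr = env.corr()
    rows = []
    cols = list(env.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = abs(float(corr.loc[a, b]))
            rows.append({"var1": a, "var2": b, "abs_r": r, "flag": r >= cutoff})
    return pd.DataFrame(rows)


def env_table(
    trees: pd.DataFrame,
    quadrats: pd.DataFrame,
    rasters: dict[str, tuple[Raster, Raster]] | None = None,
    herbs: pd.DataFrame | None = None,
    threshold_cells: float | None = None,
) -> pd.DataFrame:
    """Assemble the full environment table (raw scale, one row per quadrat).

    ``rasters`` maps plot_id -> (dem, dsm).  Standardized copies are appended
    with a ``z_`` prefix.
    """
    env = window_tree_metrics(trees, quadrats)
    if rasters is not None:
        tch, rsp = [], []
        for plot_id, (dem, dsm) in rasters.items():
            tch.append(mean_tch(dsm, dem, quadrats, plot_id=plot_id))
            rsp.append(rsp_table(dem, quadrats, plot_id=plot_id, threshold_cells=threshold_cells))
        env["meanTCH"] = pd.concat(tch).reindex(env.index)
        env["RSP"] = pd.concat(rsp).reindex(env.index)
    if herbs is not None:
        env["GHFC"] = giant_herb_cover(herbs, quadrats)["GHFC"].reindex(env.index)
    present = [c for c in ENV_COLUMNS if c in env.columns]
    z = standardize(env[present])
    z.columns = [f"z_{c}" for c in present]
    return pd.concat([env, z], axis=1)
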