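"""Readers, writers and validated in-memory containers.

All tables are plain :class:`pandas.DataFrame` objects; validation is explicit
(``validate_*`` functions raise :class:`SchemaError` naming the offending
rows).  Rasters use the ESRI ASCII grid format, the simplest interchange
format that round-trips exactly through text files.

Coordinate conventions
----------------------
Stem coordinates are plot-local metres with the origin at the plot's
lower-left corner.  Cell membership is half-open, ``[x0, x0 + side)``, so a
stem sitting exactly on a shared quadrat boundary belongs to exactly one
quadrat.  Each plot additionally has a site-level origin (``plot_x0``,
``plot_y0``) so that inter-plot distances (variograms) are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "Raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "validate_stem_table",
    "validate_liana_table",
    "validate_trait_table",
    "read_stem_table",
    "write_stem_table",
    "read_liana_table",
    "write_liana_table",
    "read_trait_table",
    "write_trait_table",
    "read_herb_grid",
    "write_herb_grid",
    "read_quadrat_frame",
    "write_quadrat_frame",
    "build_quadrat_frame",
    "build_abundance_matrix",
    "filter_min_abundance",
    "TRAIT_COLUMNS",
]

#: trait columns of the taxa x traits table (leaf and stem economics traits)
TRAIT_COLUMNS = ["Thick", "SLA", "pctC", "pctN", "pctPO4", "pctK", "TD"]


class SchemaError(ValueError):
    """A table or raster violates its schema or a type invariant."""


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


@dataclass
class Raster:
    """Regular grid (DEM / DSM / CHM).

    ``values[0, 0]`` is the north-west cell, as stored in ESRI ASCII grids;
    ``x0, y0`` is the lower-left corner of the grid.  Elevations in metres.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise SchemaError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.ndim != 2 or self.values.size == 0:
            raise SchemaError("raster must be a non-empty 2-D grid")
        data = self.values[self.values != self.nodata]
        if data.size and not np.all(np.isfinite(data)):
            raise SchemaError("raster contains non-finite values besides nodata")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of all cell centers, same shape as values."""
        cs = self.cell_size
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * cs
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return np.meshgrid(xs, ys)

    def window_values(self, xmin: float, ymin: float, xmax: float, ymax: float) -> np.ndarray:
        """Data values whose cell centers fall in [xmin, xmax) x [ymin, ymax)."""
        x, y = self.cell_centers()
        sel = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax) & self.mask()
        return self.values[sel]


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        body = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise SchemaError(f"{path}: missing ASCII grid header field {key!r}")
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - header["cellsize"] / 2
        y0 = header["yllcenter"] - header["cellsize"] / 2
    else:
        raise SchemaError(f"{path}: missing xllcorner/xllcenter")
    nodata = header.get("nodata_value", -9999.0)
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(
            f"{path}: grid body {body.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return Raster(x0=x0, y0=y0, cell_size=header["cellsize"], values=body, nodata=nodata)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {float(raster.x0)!r}\n")
        fh.write(f"yllcorner {float(raster.y0)!r}\n")
        fh.write(f"cellsize {float(raster.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata)!r}\n")
        for row in raster.values:
            # repr of a Python float is the shortest exact round-trip decimal
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# table schemas
# ---------------------------------------------------------------------------

STEM_COLUMNS = ["stem_id", "species", "plot_id", "x", "y", "dbh_census1", "dbh_census2", "wood_density"]
LIANA_COLUMNS = ["liana_id", "taxon", "quadrat_id", "diameter", "host1_stem_id", "host2_stem_id", "mechanism"]
HERB_COLUMNS = ["plot_id", "x", "y", "cover_index"]
QUADRAT_COLUMNS = [
    "quadrat_id", "plot_id", "subplot_id", "x0", "y0", "side",
    "bx0", "by0", "bside", "plot_x0", "plot_y0",
]

_MECHANISMS = {"active", "passive", "unknown"}


def _bad_rows(df: pd.DataFrame, bad: pd.Series, what: str) -> None:
    if bad.any():
        rows = list(df.index[bad][:10])
        raise SchemaError(f"{what} (rows {rows}{'...' if bad.sum() > 10 else ''})")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def validate_stem_table(df: pd.DataFrame, plot_side: float | None = None) -> pd.DataFrame:
    """Validate a tree stem table: DBH >= 10 cm where present, sane wood density."""
    _require_columns(df, STEM_COLUMNS, "stem table")
    for col in ("dbh_census1", "dbh_census2"):
        present = df[col].notna()
        _bad_rows(df, present & (df[col] < 10), f"stem table: {col} < 10 cm")
    _bad_rows(df, df["dbh_census1"].isna() & df["dbh_census2"].isna(),
              "stem table: stem absent from both censuses")
    wd = df["wood_density"]
    _bad_rows(df, ~((wd > 0.05) & (wd < 1.5)), "stem table: wood_density outside (0.05, 1.5)")
    if plot_side is not None:
        inb = (df["x"] >= 0) & (df["x"] < plot_side) & (df["y"] >= 0) & (df["y"] < plot_side)
        _bad_rows(df, ~inb, "stem table: coordinates outside plot bounds")
    if df["stem_id"].duplicated().any():
        raise SchemaError("stem table: duplicated stem_id")
    return df


def validate_liana_table(df: pd.DataFrame, stems: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a liana table: diameter >= 1 cm, hosts resolve, known mechanisms."""
    _require_columns(df, LIANA_COLUMNS, "liana table")
    _bad_rows(df, df["diameter"] < 1, "liana table: diameter < 1 cm")
    _bad_rows(df, ~df["mechanism"].isin(_MECHANISMS), "liana table: unknown climbing mechanism")
    if stems is not None:
        known = set(stems["stem_id"])
        for col in ("host1_stem_id", "host2_stem_id"):
            present = df[col].notna()
            _bad_rows(df, present & ~df[col].isin(known), f"liana table: {col} not in stem table")
    if df["liana_id"].duplicated().any():
        raise SchemaError("liana table: duplicated liana_id")
    return df


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["taxon", *TRAIT_COLUMNS], "trait table")
    if df["taxon"].duplicated().any():
        raise SchemaError("trait table: duplicated taxon")
    vals = df[TRAIT_COLUMNS]
    bad = ~(np.isfinite(vals) & (vals > 0)).all(axis=1)
    _bad_rows(df, bad, "trait table: non-finite or non-positive trait value")
    return df


def validate_herb_grid(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, HERB_COLUMNS, "herb grid")
    _bad_rows(df, ~df["cover_index"].between(1, 3), "herb grid: cover_index outside [1, 3]")
    return df


def validate_quadrat_frame(df: pd.DataFrame, buffer: float | None = None) -> pd.DataFrame:
    _require_columns(df, QUADRAT_COLUMNS, "quadrat frame")
    if df["quadrat_id"].duplicated().any():
        raise SchemaError("quadrat frame: duplicated quadrat_id")
    if buffer is not None:
        ok = (
            np.isclose(df["bx0"], df["x0"] - buffer)
            & np.isclose(df["by0"], df["y0"] - buffer)
            & np.isclose(df["bside"], df["side"] + 2 * buffer)
        )
        _bad_rows(df, ~ok, f"quadrat frame: buffered bounds != bounds expanded by {buffer} m")
    return df


# CSV dialect: UTF-8, comma separator, header row, '.' decimal -- pandas defaults.

def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_stem_table(path: str | Path, plot_side: float | None = None) -> pd.DataFrame:
    return validate_stem_table(_read_csv(path), plot_side=plot_side)


def write_stem_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_stem_table(df).to_csv(path, index=False)


def read_liana_table(path: str | Path, stems: pd.DataFrame | None = None) -> pd.DataFrame:
    return validate_liana_table(_read_csv(path), stems=stems)


def write_liana_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_liana_table(df).to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return validate_trait_table(_read_csv(path))


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_trait_table(df).to_csv(path, index=False)


def read_herb_grid(path: str | Path) -> pd.DataFrame:
    return validate_herb_grid(_read_csv(path))


def write_herb_grid(df: pd.DataFrame, path: str | Path) -> None:
    validate_herb_grid(df).to_csv(path, index=False)


def read_quadrat_frame(path: str | Path, buffer: float | None = None) -> pd.DataFrame:
    return validate_quadrat_frame(_read_csv(path), buffer=buffer)


def write_quadrat_frame(df: pd.DataFrame, path: str | Path) -> None:
    validate_quadrat_frame(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quadrat frame construction
# ---------------------------------------------------------------------------


def build_quadrat_frame(
    n_plots: int = 4,
    plot_side: float = 300.0,
    quadrat_side: float = 20.0,
    buffer: float = 10.0,
    spacing: float = 50.0,
    offset: float = 10.0,
    plot_gap: float = 200.0,
) -> pd.DataFrame:
    """Regular quadrat layout nested in square plots.

    Quadrats sit on a ``spacing``-metre lattice inside each plot (the default
    places a 20 x 20 m quadrat every 50 m, i.e. 4 quadrats per hectare and 36
    per 9-ha plot).  ``offset`` keeps the buffered 40 x 40 window inside the
    plot.  Plots themselves are laid out left to right with ``plot_gap``
    metres between them, giving every quadrat site-level coordinates for
    distance-based analyses.
    """
    per_side = int(plot_side // spacing)
    rows = []
    for p in range(n_plots):
        plot_id = f"P{p + 1}"
        plot_x0 = p * (plot_side + plot_gap)
        plot_y0 = 0.0
        q = 0
        for i in range(per_side):
            for j in range(per_side):
                x0 = i * spacing + offset
                y0 = j * spacing + offset
                q += 1
                # 1-ha subplot index (100 m cells) for the nested random-effect check
                sub = f"{plot_id}-H{int(x0 // 100) * int(np.ceil(plot_side / 100)) + int(y0 // 100) + 1}"
                rows.append({
                    "quadrat_id": f"{plot_id}-Q{q:02d}",
                    "plot_id": plot_id,
                    "subplot_id": sub,
                    "x0": x0,
                    "y0": y0,
                    "side": quadrat_side,
                    "bx0": x0 - buffer,
                    "by0": y0 - buffer,
                    "bside": quadrat_side + 2 * buffer,
                    "plot_x0": plot_x0,
                    "plot_y0": plot_y0,
                })
    return validate_quadrat_frame(pd.DataFrame(rows), buffer=buffer)


def quadrat_centers(quadrats: pd.DataFrame) -> pd.DataFrame:
    """Site-level (x, y) centers of each quadrat, indexed by quadrat_id."""
    cx = quadrats["plot_x0"] + quadrats["x0"] + quadrats["side"] / 2
    cy = quadrats["plot_y0"] + quadrats["y0"] + quadrats["side"] / 2
    return pd.DataFrame({"x": cx.values, "y": cy.values}, index=quadrats["quadrat_id"].values)


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------


def _stems_in_window(stems: pd.DataFrame, quadrats: pd.DataFrame, buffered: bool) -> pd.Series:
    """Map each stem row to a quadrat id by window membership (half-open bounds).

    With ``buffered=True`` windows overlap, so a stem may be counted in
    several quadrats; an exploded Series of (row index -> quadrat_id) is
    returned.
    """
    out_idx: list[int] = []
    out_q: list[str] = []
    for plot_id, qsub in quadrats.groupby("plot_id", sort=False):
        ssub = stems[stems["plot_id"] == plot_id]
        if ssub.empty:
            continue
        x = ssub["x"].to_numpy()
        y = ssub["y"].to_numpy()
        for _, qrow in qsub.iterrows():
            if buffered:
                x0, y0, side = qrow["bx0"], qrow["by0"], qrow["bside"]
            else:
                x0, y0, side = qrow["x0"], qrow["y0"], qrow["side"]
            sel = (x >= x0) & (x < x0 + side) & (y >= y0) & (y < y0 + side)
            out_idx.extend(ssub.index[sel])
            out_q.extend([qrow["quadrat_id"]] * int(sel.sum()))
    return pd.Series(out_q, index=out_idx, name="quadrat_id")


def build_abundance_matrix(
    table: pd.DataFrame,
    quadrats: pd.DataFrame,
    level: str = "quadrat",
    taxon_col: str | None = None,
) -> pd.DataFrame:
    """Sites x taxa count matrix.

    Lianas are recorded at quadrat resolution (``level='quadrat'`` uses their
    ``quadrat_id`` directly); trees carry coordinates and are counted in the
    buffered 40 x 40 m window (``level='buffered'``).  Rows are ordered as in
    the quadrat frame; all quadrats appear, including empty ones.
    """
    if level not in {"quadrat", "buffered"}:
        raise ValueError(f"level must be 'quadrat' or 'buffered', got {level!r}")
    qids = list(quadrats["quadrat_id"])
    if taxon_col is None:
        taxon_col = "taxon" if "taxon" in table.columns else "species"
    if level == "quadrat" and "quadrat_id" in table.columns:
        unknown = set(table["quadrat_id"]) - set(qids)
        if unknown:
            raise SchemaError(f"unknown quadrat ids: {sorted(unknown)[:5]}")
        assign = table[["quadrat_id", taxon_col]].copy()
    else:
        mapped = _stems_in_window(table, quadrats, buffered=(level == "buffered"))
        assign = pd.DataFrame({
            "quadrat_id": mapped.values,
            taxon_col: table.loc[mapped.index, taxon_col].values,
        })
    mat = pd.crosstab(assign["quadrat_id"], assign[taxon_col])
    mat = mat.reindex(index=qids, fill_value=0)
    mat.index.name = "quadrat_id"
    mat.columns.name = "taxon"
    return mat.astype(int)


def filter_min_abundance(A: pd.DataFrame, min_total: int) -> pd.DataFrame:
    """Drop taxa (columns) with fewer than ``min_total`` individuals overall."""
    return A.loc[:, A.sum(axis=0) >= min_total]
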