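"""Readers and writers for the study's tabular and raster formats.

The canonical on-disk formats are plain text: CSV tables mirroring the
supplementary-data layouts (a GPS fix table and an isotope table), ESRI
ASCII grids for rasters, GeoJSON for isopleths and YAML for configuration.
XLSX ingest is supported for the original supplementary files; since their
exact headers are not standardised, column names are resolved through a
configurable alias map.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chronology import WhiskerSeries
from .spatial import Raster, UDGrid, IsoplethResult

log = logging.getLogger("sealniche")

__all__ = [
    "SchemaError",
    "StudyConfig",
    "read_gps_table",
    "write_gps_table",
    "read_isotope_table",
    "write_isotope_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_geojson_isopleth",
    "load_config",
    "save_config",
]

TISSUES = ("plasma", "red_cells", "whisker")

GPS_ALIASES = {
    "individual": ("individual", "id", "seal", "animal", "name"),
    "sex": ("sex", "gender"),
    "timestamp": ("timestamp", "time", "date", "datetime", "gmt"),
    "lon": ("lon", "longitude", "long", "x"),
    "lat": ("lat", "latitude", "y"),
}

ISOTOPE_ALIASES = {
    "individual": ("individual", "id", "seal", "animal", "name"),
    "sex": ("sex", "gender"),
    "tissue": ("tissue", "sample", "type"),
    "section": ("section", "section_index", "segment", "n_section"),
    "d13c": ("d13c", "delta13c", "δ13c", "d13c_permil", "c13"),
    "d15n": ("d15n", "delta15n", "δ15n", "d15n_permil", "n15"),
}


class SchemaError(ValueError):
    """An expected column is missing from an input table."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _resolve_columns(df: pd.DataFrame, aliases: dict, required, optional=()) -> dict:
    lower = {str(c).strip().lower(): c for c in df.columns}
    out = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                out[canon] = lower[name]
                break
    missing = [c for c in required if c not in out]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return out


def read_gps_table(path, aliases: dict | None = None) -> pd.DataFrame:
    """Load a GPS fix table (CSV or XLSX) into the canonical layout.

    Output columns: individual, sex, timestamp (UTC), lon, lat — sorted by
    time within individual; duplicate timestamps are dropped with a warning.
    Unparseable timestamps raise with the offending row numbers.
    """
    raw = _read_table(path)
    cols = _resolve_columns(raw, {**GPS_ALIASES, **(aliases or {})},
                            required=("individual", "sex", "timestamp", "lon", "lat"))
    df = raw.rename(columns={v: k for k, v in cols.items()})
    df = df[["individual", "sex", "timestamp", "lon", "lat"]].copy()
    if df.empty:
        warnings.warn(f"{path}: GPS table has no data rows")
        return df
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=False, format="mixed")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable timestamp in row(s) {rows}")
    df["timestamp"] = ts
    df["lon"] = pd.to_numeric(df["lon"])
    df["lat"] = pd.to_numeric(df["lat"])
    if (df["lat"].abs() > 90).any():
        raise ValueError(f"{path}: latitude outside [-90, 90]")
    before = len(df)
    df = df.drop_duplicates(subset=["individual", "timestamp"])
    if len(df) < before:
        warnings.warn(f"{path}: dropped {before - len(df)} duplicate-timestamp fixes")
        log.info("dropped %d duplicate fixes from %s", before - len(df), path)
    return df.sort_values(["individual", "timestamp"]).reset_index(drop=True)


def write_gps_table(df: pd.DataFrame, path, include_flags: bool = False) -> None:
    cols = ["individual", "sex", "timestamp", "lon", "lat"]
    if include_flags and "is_outlier" in df.columns:
        cols.append("is_outlier")
    df[cols].to_csv(path, index=False)


def read_isotope_table(path, aliases: dict | None = None,
                       section_mm: float = 3.0):
    """Load an isotope table into blood samples and whisker series.

    Blood rows (tissue plasma / red_cells) become a DataFrame; whisker rows
    are assembled per individual into :class:`WhiskerSeries`, ordered by
    section index (0 = proximal).  Missing interior sections are infilled
    with NaN and flagged with a warning; an unknown tissue value raises.
    Values outside the plausible ranges δ13C ∈ [−30, −10], δ15N ∈ [5, 25]
    produce validation warnings only.
    """
    raw = _read_table(path)
    cols = _resolve_columns(raw, {**ISOTOPE_ALIASES, **(aliases or {})},
                            required=("individual", "sex", "tissue", "d13c", "d15n"))
    df = raw.rename(columns={v: k for k, v in cols.items()})
    keep = ["individual", "sex", "tissue", "d13c", "d15n"]
    if "section" in df.columns:
        keep.append("section")
    df = df[keep].copy()
    df["tissue"] = df["tissue"].astype(str).str.strip().str.lower().str.replace(" ", "_")
    unknown = ~df["tissue"].isin(TISSUES)
    if unknown.any():
        bad = sorted(df.loc[unknown, "tissue"].unique())
        raise ValueError(f"{path}: unknown tissue value(s): {bad}")
    for c in ("d13c", "d15n"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[c].notna().to_numpy())
        if bad.size:
            rows = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(f"{path}: non-numeric {c} in row(s) {rows}")
        df[c] = vals
    if ((df["d13c"] < -30) | (df["d13c"] > -10)).any():
        warnings.warn(f"{path}: some δ13C values outside the plausible [-30, -10]‰")
    if ((df["d15n"] < 5) | (df["d15n"] > 25)).any():
        warnings.warn(f"{path}: some δ15N values outside the plausible [5, 25]‰")

    blood = df[df["tissue"] != "whisker"].drop(columns=["section"], errors="ignore")
    blood = blood.reset_index(drop=True)

    whiskers = []
    wdf = df[df["tissue"] == "whisker"]
    for ind, g in wdf.groupby("individual", sort=False):
        if "section" not in g.columns:
            raise SchemaError("whisker rows require a section index column")
        g = g.sort_values("section")
        idx = g["section"].to_numpy(int)
        n = idx.max() + 1
        if idx.min() != 0 or len(idx) != n or (np.diff(idx) != 1).any():
            warnings.warn(f"{path}: non-contiguous whisker sections for {ind!r}; "
                          "gaps infilled with NaN")
        c13 = np.full(n, np.nan)
        n15 = np.full(n, np.nan)
        c13[idx] = g["d13c"].to_numpy()
        n15[idx] = g["d15n"].to_numpy()
        whiskers.append(
            WhiskerSeries(individual=str(ind), sex=str(g["sex"].iloc[0]),
                          d13c=c13, d15n=n15, section_mm=section_mm)
        )
    return blood, whiskers


def write_isotope_table(blood: pd.DataFrame, whiskers, path) -> None:
    frames = []
    if blood is not None and len(blood):
        b = blood.copy()
        b["section"] = np.nan
        frames.append(b[["individual", "sex", "tissue", "section", "d13c", "d15n"]])
    for w in whiskers or ():
        f = w.to_frame()[["individual", "sex", "section", "d13c", "d15n"]].copy()
        f.insert(2, "tissue", "whisker")
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rasters & GeoJSON
# ---------------------------------------------------------------------------


def write_ascii_grid(raster: Raster, path) -> None:
    """ESRI ASCII grid; rows written north to south as the format requires."""
    ny, nx = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {raster.x0:.6f}\n")
        fh.write(f"yllcorner {raster.y0:.6f}\n")
        fh.write(f"cellsize {raster.cell:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.values[::-1], fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    values = np.loadtxt(lines[i:])
    values = np.atleast_2d(values)[::-1]  # back to south-first rows
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    return Raster(values=values.copy(), x0=header["xllcorner"], y0=header["yllcorner"],
                  cell=header["cellsize"], nodata=header.get("nodata_value", -9999.0))


def write_geojson_isopleth(iso: IsoplethResult, ud: UDGrid, path,
                           properties: dict | None = None) -> None:
    """Isopleth cell set as a merged (Multi)Polygon GeoJSON in planar metres."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    rows, cols = np.nonzero(iso.cells)
    cells = [
        box(ud.x0 + c * ud.cell, ud.y0 + r * ud.cell,
            ud.x0 + (c + 1) * ud.cell, ud.y0 + (r + 1) * ud.cell)
        for r, c in zip(rows, cols)
    ]
    geom = unary_union(cells) if cells else box(0, 0, 0, 0)
    feature = {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": {"level": iso.level, "area_km2": iso.area_km2,
                       **(properties or {})},
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Paths plus the study constants, with the values used throughout."""

    gps_table: str | None = None
    isotope_table: str | None = None
    mask_raster: str | None = None
    output_dir: str = "."
    vmax_ms: float = 8.0
    fix_interval_s: float = 600.0
    section_mm: float = 3.0
    days_per_year: float = 365.0
    window_years: float = 2.5
    n_replicates: int = 10_000
    isopleth_levels: tuple = (0.95, 0.50)
    cell_m: float = 2000.0
    colony_lon: float = 146.3
    colony_lat: float = -39.1667
    track_days: int = 35
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("vmax_ms", "fix_interval_s", "section_mm", "days_per_year",
                     "cell_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_years < 0 or self.n_replicates < 0:
            raise ValueError("window_years and n_replicates must be >= 0")
        for lev in self.isopleth_levels:
            if not 0.0 < lev <= 1.0:
                raise ValueError("isopleth levels must be in (0, 1]")


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "isopleth_levels" in data:
        data["isopleth_levels"] = tuple(data["isopleth_levels"])
    return StudyConfig(**data)


def save_config(cfg: StudyConfig, path) -> None:
    data = asdict(cfg)
    data["isopleth_levels"] = list(cfg.isopleth_levels)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
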