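"""Readers and writers for the pipeline's file formats.

No science lives here. Relocation tables are plain CSV; utilization
distributions travel as ESRI ASCII grids; land masks come in as GeoJSON
polygons or as {land, sea} coded ASCII grids; hotspots go out as GeoJSON
FeatureCollections.

A *location table* is a pandas DataFrame with columns ``animal_id`` (str),
``timestamp`` (tz-aware UTC), ``x``, ``y`` (meters, shared planar
projection), ``lc`` (Argos location class token) and optionally
``error_radius`` (meters). After ingestion, rows are sorted by
(animal_id, timestamp) and timestamps are strictly increasing per animal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

from ._util import logger
from .grids import GridGeometry, UDGrid
from .landmask import LandMask

VALID_LC = {"3", "2", "1", "0", "A", "B", "Z"}

REQUIRED_COLUMNS = ("animal_id", "timestamp", "x", "y", "lc")


class SchemaError(ValueError):
    """A required column is missing or a field cannot be parsed."""


def _apply_column_map(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_locations(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a relocation CSV into a location table.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"animal_id": "id", "timestamp": "date"}``. Rows are sorted by
    (animal, timestamp); duplicate (animal, timestamp) rows keep the first.
    """
    df = pd.read_csv(path, dtype={"lc": str})
    df = _apply_column_map(df, column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"locations file is missing required column {col!r}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise SchemaError(
            f"unparseable timestamp {df['timestamp'].iloc[bad]!r} at data row {bad + 1}"
        )
    df = df.assign(timestamp=ts)
    df["animal_id"] = df["animal_id"].astype(str)
    df["lc"] = df["lc"].astype(str).str.strip()
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.all(np.isfinite(vals.to_numpy())):
            bad = int(np.flatnonzero(~np.isfinite(vals.to_numpy()))[0])
            raise SchemaError(f"non-finite {col} at data row {bad + 1}")
        df[col] = vals.astype(float)
    if "error_radius" in df.columns:
        df["error_radius"] = pd.to_numeric(df["error_radius"], errors="coerce")
        if (df["error_radius"] <= 0).any():
            raise SchemaError("error_radius must be positive where present")
    else:
        df["error_radius"] = np.nan
    df = df.sort_values(["animal_id", "timestamp"], kind="stable")
    n_before = len(df)
    df = df.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    df = df.reset_index(drop=True)
    logger.info(
        "read %d locations (%d duplicate rows collapsed) for %d animals",
        len(df), n_before - len(df), df["animal_id"].nunique(),
    )
    cols = ["animal_id", "timestamp", "x", "y", "lc", "error_radius"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def write_locations(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_censor(path) -> pd.DataFrame:
    """Censor table CSV: animal_id, last_valid_date (UTC date). Locations on
    or after last_valid_date are excluded downstream."""
    df = pd.read_csv(path)
    for col in ("animal_id", "last_valid_date"):
        if col not in df.columns:
            raise SchemaError(f"censor file is missing required column {col!r}")
    if df["animal_id"].duplicated().any():
        raise SchemaError("censor table has more than one row for an animal")
    df["animal_id"] = df["animal_id"].astype(str)
    df["last_valid_date"] = pd.to_datetime(df["last_valid_date"]).dt.date
    return df


# ---------------------------------------------------------------- land masks

def read_landmask(path) -> LandMask:
    """Land mask from GeoJSON (Polygon/MultiPolygon features = land) or from
    an ESRI ASCII grid of codes (1 = land, 0 = sea)."""
    text = open(path).read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        gj = json.loads(text)
        geoms = []
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for feat in feats:
            geom = feat.get("geometry", feat)
            if geom and geom.get("type") in ("Polygon", "MultiPolygon"):
                geoms.append(shape(geom))
        if not geoms:
            raise ValueError("no polygonal land features found in GeoJSON")
        land = unary_union(geoms)
        if land.is_empty:
            raise ValueError("land geometry is empty")
        return LandMask(land=land)
    # raster of land/sea codes
    grid = read_ud(path, check_normalized=False)
    land_cells = grid.values >= 0.5
    if not land_cells.any():
        raise ValueError("raster land mask contains no land cells")
    geom = grid.geometry
    boxes = []
    rows, cols = np.nonzero(land_cells)
    for r, c in zip(rows, cols):
        x0 = geom.xll + c * geom.cell_size
        y0 = geom.yll + (geom.nrows - r - 1) * geom.cell_size
        boxes.append(
            Polygon(
                [
                    (x0, y0),
                    (x0 + geom.cell_size, y0),
                    (x0 + geom.cell_size, y0 + geom.cell_size),
                    (x0, y0 + geom.cell_size),
                ]
            )
        )
    return LandMask(land=unary_union(boxes))


def write_landmask_geojson(mask: LandMask, path) -> None:
    feature = {"type": "Feature", "properties": {"role": "land"},
               "geometry": mapping(mask.land)}
    gj = {"type": "FeatureCollection", "features": [feature]}
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ------------------------------------------------------------ ESRI ASCII UDs

NODATA = -9999.0


def write_ud(grid: UDGrid, path, allow_unnormalized: bool = False) -> None:
    """Write a UD as an ESRI ASCII grid (northernmost row first).

    Refuses an unnormalized grid unless ``allow_unnormalized`` is set — count
    surfaces and code rasters use the override.
    """
    if not allow_unnormalized and not grid.is_normalized():
        raise ValueError(
            f"grid mass is {grid.total_mass:.6f}, not 1; pass "
            "allow_unnormalized=True to write a non-probability raster"
        )
    g = grid.geometry
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {float(g.xll)!r}\n")
        fh.write(f"yllcorner {float(g.yll)!r}\n")
        fh.write(f"cellsize {float(g.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(NODATA)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ud(path, check_normalized: bool = True) -> UDGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float)
    geometry = GridGeometry(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    values = np.atleast_2d(values).reshape(geometry.nrows, geometry.ncols)
    grid = UDGrid(geometry, values)
    if check_normalized and not grid.is_normalized(tol=1e-6):
        raise ValueError("raster read from file is not a normalized UD")
    return grid


# ------------------------------------------------------------------ hotspots

@dataclass
class HotspotFeature:
    """The serializable face of a hotspot (see :mod:`icefox.hotspots`)."""

    hotspot_id: str
    polygon: Polygon | MultiPolygon
    first_date: str
    last_date: str
    members: list[str]
    center_x: float
    center_y: float
    peak_attendance: int


def write_hotspots(hotspots: list[HotspotFeature], path) -> None:
    features = []
    for h in hotspots:
        if not h.polygon.is_valid:
            raise ValueError(f"hotspot {h.hotspot_id} has an invalid polygon")
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "hotspot_id": h.hotspot_id,
                    "first_date": h.first_date,
                    "last_date": h.last_date,
                    "members": list(h.members),
                    "center_x": h.center_x,
                    "center_y": h.center_y,
                    "peak_attendance": h.peak_attendance,
                },
                "geometry": mapping(h.polygon),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_hotspots(path) -> list[HotspotFeature]:
    gj = json.load(open(path))
    out = []
    for feat in gj["features"]:
        props = feat["properties"]
        out.append(
            HotspotFeature(
                hotspot_id=props["hotspot_id"],
                polygon=shape(feat["geometry"]),
                first_date=props["first_date"],
                last_date=props["last_date"],
                members=list(props["members"]),
                center_x=props["center_x"],
                center_y=props["center_y"],
                peak_attendance=int(props["peak_attendance"]),
            )
        )
    return out
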