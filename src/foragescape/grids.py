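"""Geographic grids, rasters and light-weight geospatial I/O.

The analysis exchanges everything on a regular longitude/latitude grid
(0.12 deg cells by default, matching the coarsest environmental
predictor).  Rasters are read and written as ESRI ASCII grids (plain
text, georeferenced by the six-line header) and vector data as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .geo import EARTH_RADIUS_KM

DEFAULT_CELL_DEG = 0.12


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid. ``xll, yll`` are the *lower-left cell corner*.

    Rows of associated arrays run north-to-south (row 0 = northernmost),
    the ESRI ASCII convention.
    """

    xll: float
    yll: float
    ncols: int
    nrows: int
    cell_deg: float = DEFAULT_CELL_DEG

    @property
    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cell_deg

    @property
    def lat_centers(self) -> np.ndarray:
        # north-to-south to match row order
        return self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cell_deg

    def center_mesh(self):
        """(lon, lat) 2-D arrays of cell centres, shape (nrows, ncols)."""
        return np.meshgrid(self.lon_centers, self.lat_centers)

    def cell_area_km2(self) -> np.ndarray:
        """Exact spherical area of each cell, shape (nrows, ncols)."""
        dlam = np.radians(self.cell_deg)
        lat_n = np.radians(self.yll + (np.arange(self.nrows)[::-1] + 1) * self.cell_deg)
        lat_s = lat_n - np.radians(self.cell_deg)
        band = EARTH_RADIUS_KM ** 2 * dlam * (np.sin(lat_n) - np.sin(lat_s))
        return np.tile(band[:, None], (1, self.ncols))

    def index_of(self, lon, lat):
        """(row, col) indices of the cells containing the given points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cell_deg).astype(int)
        row_s = np.floor((lat - self.yll) / self.cell_deg).astype(int)
        row = self.nrows - 1 - row_s
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside

    def same_as(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (self.ncols == other.ncols and self.nrows == other.nrows
                and abs(self.xll - other.xll) < tol
                and abs(self.yll - other.yll) < tol
                and abs(self.cell_deg - other.cell_deg) < tol)


def grid_covering(lons, lats, cell_deg: float = DEFAULT_CELL_DEG,
                  pad_cells: int = 2) -> GridSpec:
    """Smallest grid (plus padding) whose cells cover the given points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    xll = np.floor(lons.min() / cell_deg) * cell_deg - pad_cells * cell_deg
    yll = np.floor(lats.min() / cell_deg) * cell_deg - pad_cells * cell_deg
    ncols = int(np.ceil((lons.max() - xll) / cell_deg)) + pad_cells
    nrows = int(np.ceil((lats.max() - yll) / cell_deg)) + pad_cells
    return GridSpec(xll=float(xll), yll=float(yll), ncols=ncols, nrows=nrows,
                    cell_deg=cell_deg)


@dataclass
class Raster:
    """A named environmental layer on a :class:`GridSpec`; NaN marks missing."""

    name: str
    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"raster '{self.name}': values shape {self.values.shape} does not "
                f"match grid ({self.grid.nrows}, {self.grid.ncols})")

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(name=name or self.name, grid=self.grid,
                      values=np.asarray(values, dtype=float), units=self.units)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (no installed package reads this tiny text format)

_NODATA = -9999.0


def write_ascii_grid(path, raster: Raster, fmt: str = "%.10g") -> None:
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (f"ncols {g.ncols}\nnrows {g.nrows}\n"
              f"xllcorner {g.xll:.10g}\nyllcorner {g.yll:.10g}\n"
              f"cellsize {g.cell_deg:.10g}\nNODATA_value {_NODATA:g}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path, name: str | None = None) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: malformed ESRI ASCII header (missing {req})")
    grid = GridSpec(xll=header["xllcorner"], yll=header["yllcorner"],
                    ncols=int(header["ncols"]), nrows=int(header["nrows"]),
                    cell_deg=header["cellsize"])
    vals = np.atleast_2d(np.asarray(vals, dtype=float))
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(name=name or path.stem, grid=grid, values=vals)


# ---------------------------------------------------------------------------
# GeoJSON helpers

def write_geojson(path, geoms, properties=None) -> None:
    """Write geometries (+ parallel list of property dicts) as a FeatureCollection."""
    geoms = list(geoms)
    if properties is None:
        properties = [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  indent=1, sort_keys=True)


def read_geojson(path):
    """Read a GeoJSON file -> (list of shapely geometries, list of property dicts)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        feats = obj["features"]
        return ([shape(f["geometry"]) for f in feats],
                [f.get("properties") or {} for f in feats])
    if obj.get("type") == "Feature":
        return [shape(obj["geometry"])], [obj.get("properties") or {}]
    return [shape(obj)], [{}]
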