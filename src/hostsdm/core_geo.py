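"""Georeferenced raster/vector data model and shared geographic utilities.

Everything downstream (climate layers, elevation, host richness, offset
priors, suitability maps) is a :class:`Raster` on a common lon/lat
:class:`GridSpec` (WGS84, square cells, row 0 = northernmost row).
Occurrences are plain tables of (species_id, lon, lat); expert ranges are
shapely polygons.

Distances use a spherical earth with R = 6371.0 km (haversine); no
projected CRS support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon

EARTH_RADIUS_KM = 6371.0

SUITABILITY_BINS = ("unsuitable", "low", "medium", "high")
#: half-open bin edges for classify_suitability; top bin closed at 1.0
SUITABILITY_EDGES = (0.33, 0.66, 0.90)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``origin_lon``/``origin_lat`` is the *upper-left corner* of the grid
    (north-west). ``cell_size`` is in decimal degrees and cells are square;
    the conventional working resolution is 2.5 arc-min (0.0416667 deg,
    about 4.6 km at the equator).
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        east = self.origin_lon + self.n_cols * self.cell_size
        south = self.origin_lat - self.n_rows * self.cell_size
        if not (-180.0 <= self.origin_lon and east <= 180.0 + 1e-9):
            raise ValueError("grid extent exceeds [-180, 180] longitude")
        if not (south >= -90.0 - 1e-9 and self.origin_lat <= 90.0):
            raise ValueError("grid extent exceeds [-90, 90] latitude")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in degrees."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def cell_of(self, lon, lat):
        """Row/col indices by the floor convention on (coord - origin)/cell.

        A point exactly on a shared edge belongs to the cell with the larger
        index along that axis (floor rule); points on the extreme east/south
        boundary are clamped into the last cell so the closed extent maps
        onto the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # 1e-9-cell snap tolerance so points constructed on an edge land in
        # the upper cell despite floating-point representation error
        eps = 1e-9
        col = np.floor((lon - self.origin_lon) / self.cell_size + eps).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size + eps).astype(int)
        col = np.where(
            (col == self.n_cols)
            & np.isclose(lon, self.origin_lon + self.n_cols * self.cell_size),
            self.n_cols - 1,
            col,
        )
        row = np.where(
            (row == self.n_rows)
            & np.isclose(lat, self.origin_lat - self.n_rows * self.cell_size),
            self.n_rows - 1,
            row,
        )
        return row, col

    def contains(self, lon, lat):
        west, south, east, north = self.bounds
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= west) & (lon <= east) & (lat >= south) & (lat <= north)

    def cell_center(self, row, col):
        """Lon/lat of cell centers (inverse of :meth:`cell_of` up to center)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) arrays of cell-center lon and lat."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)


@dataclass
class Raster:
    """A single named layer: values plus a nodata mask on a GridSpec.

    ``nodata_mask`` is True where the cell carries no data; all statistics
    must exclude masked cells (use :meth:`valid_values`).
    """

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.spec.shape:
                raise ValueError("nodata_mask shape mismatch")

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(
            self.spec,
            np.asarray(values, dtype=float),
            self.nodata_mask.copy(),
            self.name if name is None else name,
        )

    def value_at(self, lon, lat):
        """Cell value(s) at lon/lat points (masked cells give NaN)."""
        row, col = self.spec.cell_of(lon, lat)
        vals = self.values[row, col].astype(float)
        return np.where(self.nodata_mask[row, col], np.nan, vals)


OCC_COLUMNS = ["species_id", "lon", "lat", "source"]


def make_occurrence_table(records) -> pd.DataFrame:
    """Validate and normalize an occurrence table.

    Accepts a DataFrame or an iterable of (species_id, lon, lat[, source])
    and returns a DataFrame with columns species_id, lon, lat, source.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "species" in df.columns and "species_id" not in df.columns:
            df = df.rename(columns={"species": "species_id"})
    else:
        rows = []
        for rec in records:
            rec = list(rec)
            if len(rec) == 3:
                rec.append(None)
            rows.append(rec)
        df = pd.DataFrame(rows, columns=OCC_COLUMNS)
    if "source" not in df.columns:
        df["source"] = None
    df = df[OCC_COLUMNS].reset_index(drop=True)
    if (df["species_id"].astype(str).str.len() == 0).any():
        raise ValueError("species_id must be non-empty")
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
        raise ValueError("coordinates outside WGS84 bounds")
    return df


def read_occurrences(path) -> pd.DataFrame:
    """Read a `species,lon,lat[,source]` CSV."""
    return make_occurrence_table(pd.read_csv(path))


def write_occurrences(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"species_id": "species"})
    out.to_csv(path, index=False)


def thin_occurrences(occ: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Retain at most one record per grid cell per species.

    Tie-break: the first record in input order wins; output preserves input
    order, which makes thinning deterministic and idempotent.
    """
    occ = make_occurrence_table(occ)
    inside = spec.contains(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"occurrence record {bad} falls outside the grid extent")
    row, col = spec.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    key = pd.DataFrame(
        {"species_id": occ["species_id"].to_numpy(), "row": row, "col": col}
    )
    keep = ~key.duplicated()
    return occ.loc[keep].reset_index(drop=True)


def equatorial_cell_width_km(cell_size: float) -> float:
    """Arc length of one cell at the equator, spherical earth R=6371 km."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    return cell_size * math.pi / 180.0 * EARTH_RADIUS_KM


def classify_suitability(p):
    """Four-way suitability bins used to reclassify model output.

    Bins follow the IPCC likelihood cut-points: [0,0.33) unsuitable,
    [0.33,0.66) low, [0.66,0.90) medium, [0.90,1.0] high.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("suitability must lie in [0, 1]")
    idx = np.digitize(arr, SUITABILITY_EDGES, right=False)
    if arr.ndim == 0:
        return SUITABILITY_BINS[int(idx)]
    return np.asarray(SUITABILITY_BINS, dtype=object)[idx]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _polygon_rings(polygon):
    if isinstance(polygon, MultiPolygon):
        polys = list(polygon.geoms)
    elif isinstance(polygon, Polygon):
        polys = [polygon]
    else:
        raise ValueError("expected a shapely Polygon or MultiPolygon")
    rings = []
    for p in polys:
        rings.append(np.asarray(p.exterior.coords))
        for hole in p.interiors:
            rings.append(np.asarray(hole.coords))
    return rings


def _point_segment_distance_km(lon, lat, ax, ay, bx, by):
    """Distance from points to segments, equirectangular local approximation.

    Adequate at the desk scales used here (segments much shorter than the
    earth radius); endpoint distances use the exact haversine as a floor.
    """
    lat0 = np.radians((np.mean(ay) + np.mean(by)) / 2.0)
    kx = EARTH_RADIUS_KM * math.pi / 180.0 * math.cos(lat0)
    ky = EARTH_RADIUS_KM * math.pi / 180.0
    px = (lon[:, None] - ax[None, :]) * kx
    py = (lat[:, None] - ay[None, :]) * ky
    dx = (bx - ax)[None, :] * kx
    dy = (by - ay)[None, :] * ky
    seg2 = dx * dx + dy * dy
    t = np.where(seg2 > 0, (px * dx + py * dy) / np.where(seg2 > 0, seg2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    ex = px - t * dx
    ey = py - t * dy
    return np.sqrt(ex * ex + ey * ey)


def signed_distance_to_range(lons, lats, polygon) -> np.ndarray:
    """Great-circle distance (km) to the range boundary; negative inside.

    Sign convention: negative for points strictly inside the polygon,
    positive outside, zero on the boundary.
    """
    if polygon is None or polygon.is_empty or polygon.area <= 0:
        raise ValueError("degenerate range polygon")
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    rings = _polygon_rings(polygon)
    dmin = np.full(lons.shape, np.inf)
    for ring in rings:
        ax, ay = ring[:-1, 0], ring[:-1, 1]
        bx, by = ring[1:, 0], ring[1:, 1]
        d = _point_segment_distance_km(lons, lats, ax, ay, bx, by)
        dmin = np.minimum(dmin, d.min(axis=1))
    from shapely import contains_xy

    # boundary points have dmin == 0, so the sign is immaterial there
    inside = contains_xy(polygon, lons, lats)
    return np.where(inside, -1.0, 1.0) * dmin


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid (text) and single-band GeoTIFF via tifffile.

_NODATA = -9999.0

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113
# GeoKeys: model type geographic (2), raster pixel-is-area (1), WGS84 (4326)
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_esri_ascii(raster: Raster, path) -> None:
    spec = raster.spec
    west, south, _, _ = spec.bounds
    vals = np.where(raster.nodata_mask, _NODATA, raster.values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {west!r}\n"
        f"yllcorner {south!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in range(spec.n_rows):
            fh.write(" ".join(repr(float(v)) for v in vals[r]) + "\n")


def read_esri_ascii(path, name: str = "") -> Raster:
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = parts[1]
        data = np.loadtxt(fh)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = float(header["cellsize"])
    west = float(header["xllcorner"])
    south = float(header["yllcorner"])
    nodata = float(header.get("nodata_value", _NODATA))
    data = data.reshape(n_rows, n_cols)
    spec = GridSpec(west, south + n_rows * cell, cell, n_rows, n_cols)
    mask = data == nodata
    return Raster(spec, np.where(mask, np.nan, data), mask, name=name)


def write_geotiff(raster: Raster, path, dtype=np.float32) -> None:
    """Single-band GeoTIFF with WGS84 georeferencing and a nodata tag."""
    import tifffile

    spec = raster.spec
    vals = np.where(raster.nodata_mask, _NODATA, raster.values).astype(dtype)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_lon, spec.origin_lat, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_GDAL_NODATA, "s", 0, str(_NODATA)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path, name: str = "") -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = {tag.code: tag.value for tag in page.tags.values()}
    scale = tags[_MODEL_PIXEL_SCALE]
    tie = tags[_MODEL_TIEPOINT]
    nodata = float(tags.get(_GDAL_NODATA, _NODATA))
    cell = float(scale[0])
    origin_lon = float(tie[3])
    origin_lat = float(tie[4])
    n_rows, n_cols = data.shape
    spec = GridSpec(origin_lon, origin_lat, cell, n_rows, n_cols)
    mask = data == nodata
    return Raster(spec, np.where(mask, np.nan, data), mask, name=name)


def write_geojson(polygon, path) -> None:
    import json

    from shapely.geometry import mapping

    with open(path, "w") as fh:
        json.dump(
            {
                "type": "Feature",
                "properties": {},
                "geometry": mapping(polygon),
            },
            fh,
        )


def read_geojson(path):
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    return shape(obj)
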