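"""Raster and occurrence-table I/O plus great-circle geometry.

All rasters are single-band GeoTIFFs in geographic WGS84 coordinates.  The
grid convention used throughout the package is fixed here: cells are
half-open intervals whose west and north edges are inclusive, coordinates
refer to cell centers, and point-to-cell assignment is nearest-cell (no
interpolation) so that training features and per-cell predictions are drawn
from identical values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEGREE",
    "RasterGrid",
    "PredictorStack",
    "OccurrenceTable",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "extract_values",
    "great_circle_km",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: Length of one degree of latitude (and of longitude at the equator), km.
KM_PER_DEGREE = 111.32

_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A single 2-D raster layer on a geographic (WGS84) grid.

    Parameters
    ----------
    values
        Cell values, shape ``(n_rows, n_cols)``; row 0 is the northernmost.
    mask
        Boolean nodata mask, same shape; ``True`` marks masked cells.
    west, north
        Coordinates of the outer edge of the top-left cell, decimal degrees.
    cell_deg
        Cell size in decimal degrees (square cells).
    """

    values: np.ndarray
    mask: np.ndarray
    west: float
    north: float
    cell_deg: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        if self.cell_deg <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.west, other.west, abs_tol=1e-9)
            and math.isclose(self.north, other.north, abs_tol=1e-9)
            and math.isclose(self.cell_deg, other.cell_deg, rel_tol=1e-12)
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of cell centers for (arrays of) indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.west + (col + 0.5) * self.cell_deg
        lat = self.north - (row + 0.5) * self.cell_deg
        return lon, lat

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to (row, col, inside) under half-open cells.

        The west and north edges of each cell are inclusive; points outside
        the grid get ``inside=False`` and clipped indices.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # 1e-9-cell snap so points exactly on an edge resolve east/south of
        # it despite floating-point rounding
        col = np.floor((lon - self.west) / self.cell_deg + 1e-9).astype(int)
        row = np.floor((self.north - lat) / self.cell_deg + 1e-9).astype(int)
        # a point exactly on the south/east outer edge belongs to no cell
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return (
            np.clip(row, 0, self.n_rows - 1),
            np.clip(col, 0, self.n_cols - 1),
            inside,
        )

    def copy(self, values: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            values=self.values.copy() if values is None else np.asarray(values, float),
            mask=self.mask.copy(),
            west=self.west,
            north=self.north,
            cell_deg=self.cell_deg,
        )

    def unmasked_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(~self.mask)


@dataclass
class PredictorStack:
    """Named, co-registered predictor layers for one climate scenario."""

    scenario: str
    grids: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grids:
            ref = next(iter(self.grids.values()))
            for name, g in self.grids.items():
                if not g.same_grid(ref):
                    raise ValueError(f"layer {name!r} is not co-registered with the stack")
                if not np.array_equal(g.mask, ref.mask):
                    raise ValueError(f"layer {name!r} has a different nodata mask")

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def grid(self) -> RasterGrid:
        if not self.grids:
            raise ValueError("empty predictor stack")
        return next(iter(self.grids.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Feature matrix over unmasked cells, shape (n_unmasked, n_predictors)."""
        names = names or self.names
        rows, cols = self.grid.unmasked_indices()
        return np.column_stack([self.grids[n].values[rows, cols] for n in names])


@dataclass
class OccurrenceTable:
    """Species presence coordinates in decimal degrees (WGS84)."""

    species_id: str
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon and lat must have equal length")

    def __len__(self) -> int:
        return self.lon.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Lon": self.lon, "Lat": self.lat})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a RasterGrid as a single-band float32 GeoTIFF (WGS84)."""
    path = Path(path)
    vals = grid.values.astype(np.float32).copy()
    vals[grid.mask] = _NODATA
    geokeys = (
        1, 1, 0, 4,
        1024, 0, 1, 2,       # model type: geographic
        1025, 0, 1, 1,       # raster type: pixel-is-area
        2048, 0, 1, 4326,    # geographic CRS: WGS84
        2049, _TAG_GEO_ASCII, 7, 0,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, 12, 3, (grid.cell_deg, grid.cell_deg, 0.0)),
        (_TAG_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, grid.west, grid.north, 0.0)),
        (_TAG_GEO_KEYS, 3, len(geokeys), geokeys),
        (_TAG_GEO_ASCII, 2, None, "WGS 84|"),
        (_TAG_GDAL_NODATA, 2, None, str(_NODATA)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band geographic GeoTIFF into a RasterGrid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1 or len(page.shape) != 2:
            raise ValueError(f"expected a single-band raster: {path}")
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"missing GeoTIFF georeferencing tags: {path}")
        keys_tag = page.tags.get(_TAG_GEO_KEYS)
        if keys_tag is not None:
            keys = list(keys_tag.value)
            # GTModelTypeGeoKey (1024): 2 = geographic; anything else rejected
            for i in range(4, len(keys) - 3, 4):
                if keys[i] == 1024 and keys[i + 3] != 2:
                    raise ValueError(f"non-geographic CRS in raster: {path}")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise ValueError(f"non-square cells in raster: {path}")
        west, north = float(tie_tag.value[3]), float(tie_tag.value[4])
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else _NODATA
        vals = page.asarray().astype(float)
    mask = ~np.isfinite(vals) | np.isclose(vals, nodata)
    vals = vals.copy()
    vals[mask] = np.nan
    return RasterGrid(values=vals, mask=mask, west=west, north=north, cell_deg=sx)


def read_occurrences(path: str | Path, species_id: str | None = None) -> OccurrenceTable:
    """Load an occurrence CSV with (case-insensitive) Lon/Lat columns.

    Unparsable or out-of-range coordinates are dropped with a logged count;
    exact duplicate coordinates are collapsed to one record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence file not found: {path}")
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "lon" not in cols or "lat" not in cols:
        raise ValueError(f"occurrence file must have Lon and Lat columns: {path}")
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d invalid coordinate rows", path.name, n_dropped)
    out = pd.DataFrame({"lon": lon[ok], "lat": lat[ok]}).drop_duplicates()
    return OccurrenceTable(
        species_id=species_id or path.stem,
        lon=out["lon"].to_numpy(),
        lat=out["lat"].to_numpy(),
    )


def extract_values(
    stack: PredictorStack,
    lon: np.ndarray,
    lat: np.ndarray,
    names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictor values of the cell containing each point.

    Returns ``(features, keep)`` where ``features`` has one column per
    predictor and ``keep`` is ``False`` for points outside the grid or on
    masked cells (their feature rows are NaN).
    """
    if not stack.grids:
        raise ValueError("empty predictor stack")
    names = names or stack.names
    grid = stack.grid
    row, col, inside = grid.index_of(lon, lat)
    keep = inside & ~grid.mask[row, col]
    feats = np.full((np.size(lon), len(names)), np.nan)
    if keep.any():
        r, c = row[keep], col[keep]
        for j, n in enumerate(names):
            feats[keep, j] = stack.grids[n].values[r, c]
    return feats, keep


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine distance in km on a sphere of radius 6371 km.

    Broadcasts over array inputs; handles the antimeridian correctly.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d
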