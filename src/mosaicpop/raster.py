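"""Geographic grid definition and plain-text raster I/O.

The output grid is 3 arc-seconds (1/1200 degree, roughly 90 m) in WGS84
geographic coordinates, with cell edges snapped to integer multiples of the
cell size from (-180, -90) so independently produced tiles align.  Rasters
are written as ESRI ASCII grids (one ``.asc`` file per band), a text format
any GIS reads; georeferencing lives in the header, CRS is implicitly WGS84
and recorded in a ``.prj``-style sidecar line inside the header comment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from shapely.geometry import box

#: 3 arc-seconds in degrees.
CELLSIZE_3AS = 1.0 / 1200.0

DEFAULT_NODATA = -1.0


@dataclass(frozen=True)
class GridSpec:
    """A north-up regular grid in geographic coordinates.

    ``west``/``south`` are the outer edges; row 0 is the northernmost row.
    """

    west: float
    south: float
    ncols: int
    nrows: int
    cellsize: float = CELLSIZE_3AS

    @classmethod
    def from_extent(
        cls,
        lon_min: float,
        lat_min: float,
        lon_max: float,
        lat_max: float,
        cellsize: float = CELLSIZE_3AS,
    ) -> "GridSpec":
        """Smallest aligned grid covering the extent (edges snapped outward)."""
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ValueError("degenerate extent")
        inv = 1.0 / cellsize
        c0 = math.floor((lon_min + 180.0) * inv)
        c1 = math.ceil((lon_max + 180.0) * inv)
        r0 = math.floor((lat_min + 90.0) * inv)
        r1 = math.ceil((lat_max + 90.0) * inv)
        return cls(
            west=c0 * cellsize - 180.0,
            south=r0 * cellsize - 90.0,
            ncols=c1 - c0,
            nrows=r1 - r0,
            cellsize=cellsize,
        )

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0 = self.west + col * self.cellsize
        y1 = self.north - row * self.cellsize
        return (x0, y1 - self.cellsize, x0 + self.cellsize, y1)

    def cell_polygon(self, row: int, col: int):
        return box(*self.cell_bounds(row, col))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinates, each of shape (nrows, ncols)."""
        lon = self.west + (np.arange(self.ncols) + 0.5) * self.cellsize
        lat = self.north - (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def locate(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; may be out of range."""
        col = int(math.floor((lon - self.west) / self.cellsize))
        row = int(math.floor((self.north - lat) / self.cellsize))
        return row, col

    def iter_cells_overlapping(
        self, lon_min: float, lat_min: float, lon_max: float, lat_max: float
    ) -> Iterator[tuple[int, int]]:
        c0 = max(0, int(math.floor((lon_min - self.west) / self.cellsize)))
        c1 = min(self.ncols - 1, int(math.floor((lon_max - self.west) / self.cellsize)))
        r0 = max(0, int(math.floor((self.north - lat_max) / self.cellsize)))
        r1 = min(self.nrows - 1, int(math.floor((self.north - lat_min) / self.cellsize)))
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                yield r, c


@dataclass
class QuantileRaster:
    """Multi-band raster of per-cell population quantiles and derivatives."""

    grid: GridSpec
    bands: dict[str, np.ndarray] = field(default_factory=dict)
    nodata: float = DEFAULT_NODATA
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"band {name!r} shape {arr.shape} != grid {self.grid.shape}")

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]

    def valid_mask(self, name: str) -> np.ndarray:
        return self.bands[name] != self.nodata


def write_ascii_grid(
    array: np.ndarray, grid: GridSpec, path, nodata: float = DEFAULT_NODATA
) -> None:
    """Write one band as an ESRI ASCII grid (row 0 = north)."""
    arr = np.where(np.isnan(array), nodata, array)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.west!r}\n")
        fh.write(f"yllcorner {grid.south!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in arr:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns (array, grid, nodata)."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=np.float32))
    grid = GridSpec(
        west=header["xllcorner"],
        south=header["yllcorner"],
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        cellsize=header["cellsize"],
    )
    arr = np.vstack(rows).astype(np.float32)
    if arr.shape != grid.shape:
        raise ValueError(f"data shape {arr.shape} does not match header {grid.shape}")
    return arr, grid, header.get("nodata_value", DEFAULT_NODATA)


def intersect_grids(
    a: np.ndarray, ga: GridSpec, b: np.ndarray, gb: GridSpec
) -> tuple[np.ndarray, np.ndarray, GridSpec]:
    """Crop two co-aligned rasters to their common extent.

    Both grids must share cellsize and edge alignment (which the snapped
    grid construction guarantees); the result covers the intersection.
    """
    if not math.isclose(ga.cellsize, gb.cellsize):
        raise ValueError("grids have different cell sizes")
    for off in ((ga.west - gb.west), (ga.south - gb.south)):
        if abs(off / ga.cellsize - round(off / ga.cellsize)) > 1e-6:
            raise ValueError("grids are not edge-aligned")
    west = max(ga.west, gb.west)
    south = max(ga.south, gb.south)
    east = min(ga.east, gb.east)
    north = min(ga.north, gb.north)
    if east <= west or north <= south:
        raise ValueError("grids do not overlap")
    ncols = round((east - west) / ga.cellsize)
    nrows = round((north - south) / ga.cellsize)

    def _crop(arr, g):
        c0 = round((west - g.west) / g.cellsize)
        r0 = round((g.north - north) / g.cellsize)
        return arr[r0:r0 + nrows, c0:c0 + ncols]

    out = GridSpec(west=west, south=south, ncols=ncols, nrows=nrows,
                   cellsize=ga.cellsize)
    return _crop(a, ga), _crop(b, gb), out


def write_raster(raster: QuantileRaster, prefix) -> list[str]:
    """Write every band as ``<prefix>_<band>.asc``; returns the paths."""
    paths = []
    for name, arr in raster.bands.items():
        p = f"{prefix}_{name}.asc"
        write_ascii_grid(arr.astype(np.float32), raster.grid, p, raster.nodata)
        paths.append(p)
    return paths
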