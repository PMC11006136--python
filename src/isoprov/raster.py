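"""Georeferenced 2D grids and great-circle geodesy.

A :class:`RasterGrid` is a plain numpy array with an affine geotransform in
geographic (lon/lat, WGS84) coordinates, row 0 northernmost, cell registration
at centers.  Nodata is carried as NaN in memory and as a sentinel on disk.
Text I/O uses the ESRI ASCII grid format plus a JSON sidecar for the CRS and
arbitrary provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "RasterGrid",
    "GridTransform",
    "haversine_km",
    "destination_point",
    "EARTH_RADIUS_KM",
]


@dataclass(frozen=True)
class GridTransform:
    """Affine geotransform: top-left corner and signed cell sizes (degrees).

    ``dy`` is negative (row index increases southwards).
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise ValueError("cell sizes must be nonzero")

    def cell_center(self, row, col):
        """Lon/lat of cell center(s) for (possibly array) indices."""
        lon = self.x0 + (np.asarray(col) + 0.5) * self.dx
        lat = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def index_of(self, lon, lat):
        """Row/col of the cell containing the point(s); may be out of range."""
        col = np.floor((np.asarray(lon) - self.x0) / self.dx).astype(int)
        row = np.floor((np.asarray(lat) - self.y0) / self.dy).astype(int)
        return row, col


@dataclass
class RasterGrid:
    """A single-band georeferenced surface.

    Parameters
    ----------
    values : 2D float array; NaN marks nodata.
    transform : the grid geotransform.
    crs : CRS identifier, default geographic WGS84.
    metadata : free-form provenance (seed, units, parameters).
    """

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def cell_centers(self):
        """(lon, lat) 2D arrays of every cell center."""
        nr, nc = self.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        return self.transform.cell_center(rows, cols)

    def contains(self, lon: float, lat: float) -> bool:
        row, col = self.transform.index_of(lon, lat)
        nr, nc = self.shape
        return bool(0 <= row < nr and 0 <= col < nc)

    def value_at(self, lon: float, lat: float) -> float:
        """Value of the containing cell; raises if the point is off-grid."""
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside raster footprint")
        row, col = self.transform.index_of(lon, lat)
        return float(self.values[row, col])

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        """Co-registration check: same shape, geotransform and CRS."""
        t, u = self.transform, other.transform
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and abs(t.x0 - u.x0) <= tol
            and abs(t.y0 - u.y0) <= tol
            and abs(t.dx - u.dx) <= tol
            and abs(t.dy - u.dy) <= tol
        )

    def copy_with(self, values: np.ndarray, **metadata) -> "RasterGrid":
        """New raster on the same grid with different values."""
        md = dict(self.metadata)
        md.update(metadata)
        return RasterGrid(np.asarray(values, dtype=float), self.transform, self.crs, md)

    # -- I/O -------------------------------------------------------------
    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        """Write an ESRI ASCII grid plus a ``.json`` sidecar.

        The format carries a single cellsize, so cells must be square in
        degrees (|dx| == |dy|).
        """
        path = Path(path)
        t = self.transform
        if abs(abs(t.dx) - abs(t.dy)) > 1e-12:
            raise ValueError("ESRI ASCII grids require square cells (|dx| == |dy|)")
        nr, nc = self.shape
        yll = t.y0 + nr * t.dy  # dy < 0: bottom edge
        out = np.where(np.isfinite(self.values), self.values, nodata)
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {t.x0!r}\nyllcorner {yll!r}\n"
            f"cellsize {abs(t.dx)!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")
        sidecar = {"crs": self.crs, "metadata": self.metadata}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=str))

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nodata = header["nodata_value"]
        values[values == nodata] = np.nan
        cs = header["cellsize"]
        nr = int(header["nrows"])
        transform = GridTransform(
            x0=header["xllcorner"], y0=header["yllcorner"] + nr * cs, dx=cs, dy=-cs
        )
        crs, metadata = "EPSG:4326", {}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            crs = side.get("crs", crs)
            metadata = side.get("metadata", {})
        return cls(values, transform, crs, metadata)


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination_point(lon, lat, bearing_deg, distance_km, radius_km: float = EARTH_RADIUS_KM):
    """Point reached travelling ``distance_km`` at ``bearing_deg`` (clockwise from north)."""
    lam1, phi1, theta = (np.radians(np.asarray(x, dtype=float)) for x in (lon, lat, bearing_deg))
    delta = np.asarray(distance_km, dtype=float) / radius_km
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(lam2), np.degrees(phi2)
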