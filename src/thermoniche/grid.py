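"""Regular lon/lat raster grids shared by every pipeline stage.

A :class:`RasterGrid` stores one named covariate on a regular geographic grid.
Cell ``(i, j)`` covers the half-open box
``[lon0 + j*d, lon0 + (j+1)*d) x [lat0 + i*d, lat0 + (i+1)*d)`` where ``d`` is
the cell size in degrees and ``(lon0, lat0)`` is the lower-left corner of the
grid; row 0 is the southernmost row.  Centroids sit at box centers.  Every
stage (occurrence thinning, covariate extraction, background sampling) indexes
through this one convention so boundary points resolve deterministically.

Missing values are NaN in memory and a ``nodata`` sentinel on disk.  Grids are
serialized as ESRI ASCII grids, a plain-text raster format readable by
standard GIS tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean km per degree of latitude / of longitude at the equator.
KM_PER_DEG_LAT = 110.57
KM_PER_DEG_LON_EQ = 111.32

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A named covariate on a regular lon/lat cell grid."""

    name: str
    origin: tuple[float, float]  # (lon0, lat0), lower-left corner
    cell_size: float  # degrees
    values: np.ndarray  # (n_rows, n_cols); row 0 = southernmost; NaN = missing

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the gridded box."""
        lon0, lat0 = self.origin
        return (
            lon0,
            lat0,
            lon0 + self.n_cols * self.cell_size,
            lat0 + self.n_rows * self.cell_size,
        )

    # ---- indexing -------------------------------------------------------

    def cell_index(self, lon, lat):
        """Row/col of the half-open cell containing each point.

        Raises ``ValueError`` if any point falls outside the gridded extent.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon0, lat0 = self.origin
        j = np.floor((lon - lon0) / self.cell_size).astype(int)
        i = np.floor((lat - lat0) / self.cell_size).astype(int)
        bad = (i < 0) | (i >= self.n_rows) | (j < 0) | (j >= self.n_cols)
        if np.any(bad):
            k = int(np.argmax(np.atleast_1d(bad)))
            raise ValueError(
                f"point (lon={np.atleast_1d(lon)[k]}, lat={np.atleast_1d(lat)[k]}) "
                "is outside the grid extent"
            )
        return i, j

    def contains(self, lon, lat):
        """Boolean mask of points inside the gridded extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon_min, lat_min, lon_max, lat_max = self.extent
        return (lon >= lon_min) & (lon < lon_max) & (lat >= lat_min) & (lat < lat_max)

    def value_at(self, lon, lat):
        i, j = self.cell_index(lon, lat)
        return self.values[i, j]

    def centroid(self, i, j):
        """Lon/lat of cell centers for row/col indices."""
        lon0, lat0 = self.origin
        lon = lon0 + (np.asarray(j) + 0.5) * self.cell_size
        lat = lat0 + (np.asarray(i) + 0.5) * self.cell_size
        return lon, lat

    def centroid_grids(self):
        """(lon, lat) 2-D arrays of every cell centroid."""
        i, j = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        return self.centroid(i, j)

    def cell_id(self, i, j):
        """Flat integer id, row-major."""
        return np.asarray(i) * self.n_cols + np.asarray(j)

    def id_to_index(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def like(self, name: str, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's geometry."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template grid")
        return RasterGrid(name, self.origin, self.cell_size, values)

    # ---- text serialization (ESRI ASCII grid) ---------------------------

    def to_ascii(self, path) -> None:
        vals = np.where(np.isnan(self.values), _NODATA, self.values)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]!r}\n"
            f"yllcorner {self.origin[1]!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids are written north-to-south
            np.savetxt(fh, vals[::-1], fmt="%.10g")

    @classmethod
    def from_ascii(cls, path, name: str | None = None) -> "RasterGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)[::-1].copy()
        vals[vals == meta.get("nodata_value", _NODATA)] = np.nan
        return cls(
            name or str(path),
            (meta["xllcorner"], meta["yllcorner"]),
            meta["cellsize"],
            vals,
        )


def equirect_km(lon, lat, ref_lat: float):
    """Project lon/lat to a planar km frame (equirectangular at ``ref_lat``).

    Adequate over the few-degree synthetic extents this package works at; the
    200-km accessibility buffer stays meaningful without geodesic machinery.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = lon * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(ref_lat))
    y = lat * KM_PER_DEG_LAT
    return x, y
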