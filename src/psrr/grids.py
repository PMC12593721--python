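"""Regular-grid raster containers and a plain-text raster format.

All grids live in a planar, metric coordinate system with distances in
kilometres.  ``values[..., row, col]`` is laid out with row 0 at the *bottom*
of the domain, so the y coordinate increases with the row index.  Missing
data are NaN.

Rasters are persisted as a one-line JSON header followed by the flattened
array in whitespace-separated text, so every artifact the pipeline writes is
portable and diffable.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RasterGrid",
    "ProductivityStack",
    "DHIRaster",
    "write_raster",
    "read_raster",
]


@dataclass
class RasterGrid:
    """A single- or multi-band raster on a regular grid.

    Parameters
    ----------
    values : ndarray
        2-D ``(rows, cols)`` or 3-D ``(bands, rows, cols)`` array; NaN marks
        nodata.
    resolution_km : float
        Pixel edge length in km.
    origin : tuple of float
        ``(x, y)`` of the *lower-left corner* of pixel ``[0, 0]`` in km.
    """

    values: np.ndarray
    resolution_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "planar-km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D or 3-D")
        if self.resolution_km <= 0:
            raise ValueError("resolution_km must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[-2]

    @property
    def n_cols(self) -> int:
        return self.values.shape[-1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` 1-D arrays of column / row center coordinates."""
        res = self.resolution_km
        x = self.origin[0] + (np.arange(self.n_cols) + 0.5) * res
        y = self.origin[1] + (np.arange(self.n_rows) + 0.5) * res
        return x, y

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D meshgrids of pixel-center coordinates, shaped like a band."""
        x, y = self.pixel_centers()
        return np.meshgrid(x, y)


@dataclass
class ProductivityStack:
    """Time-indexed cube of GPP composites (kg C/m^2 per composite).

    ``composite_days`` is the nominal compositing period in days (8 for the
    8-day product); ``monthly=True`` flags a stack whose layers are already
    monthly totals, in which case monthly aggregation is the identity.
    """

    values: np.ndarray  # (time, rows, cols)
    composite_start_dates: list[_dt.date]
    resolution_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    composite_days: int = 8
    monthly: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("stack values must be (time, rows, cols)")
        if len(self.composite_start_dates) != self.values.shape[0]:
            raise ValueError(
                "composite_start_dates length must match the time dimension"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("GPP values must be non-negative or nodata")

    @property
    def grid(self) -> RasterGrid:
        return RasterGrid(self.values[0], self.resolution_km, self.origin)

    def years(self) -> list[int]:
        return sorted({d.year for d in self.composite_start_dates})


@dataclass
class DHIRaster:
    """Per-pixel dynamic habitat indices averaged across years.

    Bands: cumulative ``sum`` (kg C/m^2/year), ``minimum`` (kg C/m^2/month)
    and ``seasonality`` (coefficient of variation, dimensionless).
    """

    sum: np.ndarray
    minimum: np.ndarray
    seasonality: np.ndarray
    resolution_km: float
    origin: tuple[float, float] = (0.0, 0.0)

    BAND_NAMES = ("sum", "minimum", "seasonality")

    def __post_init__(self) -> None:
        for name in self.BAND_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        shapes = {getattr(self, n).shape for n in self.BAND_NAMES}
        if len(shapes) != 1:
            raise ValueError("DHI bands must share one shape")

    def band(self, name: str) -> RasterGrid:
        if name not in self.BAND_NAMES:
            raise KeyError(f"unknown DHI band {name!r}")
        return RasterGrid(getattr(self, name), self.resolution_km, self.origin)

    def as_grid(self) -> RasterGrid:
        stacked = np.stack([getattr(self, n) for n in self.BAND_NAMES])
        return RasterGrid(stacked, self.resolution_km, self.origin)


def write_raster(path, grid: RasterGrid, band_names: list[str] | None = None) -> None:
    """Write a raster as a JSON header line plus flattened text values."""
    header = {
        "shape": list(grid.values.shape),
        "resolution_km": grid.resolution_km,
        "origin": list(grid.origin),
        "crs": grid.crs_tag,
        "nodata": "nan",
    }
    if band_names is not None:
        header["band_names"] = list(band_names)
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, grid.values.reshape(1, -1), fmt="%.10g")


def read_raster(path) -> RasterGrid:
    with open(path) as fh:
        header = json.loads(fh.readline())
        flat = np.loadtxt(fh)
    values = flat.reshape(header["shape"])
    return RasterGrid(
        values,
        header["resolution_km"],
        tuple(header["origin"]),
        header.get("crs", "planar-km"),
    )
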