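"""Dynamic habitat indices from an intra-annual GPP stack.

Three per-pixel indices summarize the productivity year: the cumulative
``sum`` (available energy), the ``minimum`` monthly value (the
environmental-stress bottleneck) and the ``seasonality`` (coefficient of
variation, resource instability).  Yearly values are averaged across years.

Conventions, fixed here and used consistently everywhere:

* 8-day composites belong to the month containing their start date; the
  monthly total is the mean composite value scaled by ``days_in_month / 8``.
* Standard deviations (both the CV and covariate standardization) use the
  sample (n-1) denominator.
* A pixel whose monthly mean is zero gets seasonality 0 (deserts with zero
  GPP are a defined, not missing, case).
* Buffer membership is decided by pixel-center distance.
"""

from __future__ import annotations

import calendar

import numpy as np

from .grids import DHIRaster, ProductivityStack, RasterGrid

__all__ = [
    "aggregate_to_monthly",
    "compute_dhi",
    "compute_dhi_from_stack",
    "aggregate_pixels",
    "aggregate_majority",
    "buffer_mean",
    "standardize",
]


def aggregate_to_monthly(stack: ProductivityStack, year: int) -> np.ndarray:
    """Aggregate one year of composites to 12 monthly-total layers.

    Returns a ``(12, rows, cols)`` array.  Each composite is assigned to the
    month containing its start date; the monthly value is the mean of those
    composites scaled by ``days_in_month / composite_days``.  A stack flagged
    ``monthly=True`` is passed through unchanged.  A month with no composites
    raises, naming the month.
    """
    dates = stack.composite_start_dates
    idx_year = [i for i, d in enumerate(dates) if d.year == year]
    if not idx_year:
        raise ValueError(f"stack does not cover year {year}")
    if stack.monthly:
        months = [dates[i].month for i in idx_year]
        if sorted(months) != list(range(1, 13)):
            raise ValueError(f"monthly stack for year {year} lacks all 12 months")
        order = np.argsort(months)
        return stack.values[np.array(idx_year)[order]]

    layers = []
    for month in range(1, 13):
        sel = [i for i in idx_year if dates[i].month == month]
        if not sel:
            raise ValueError(f"no composites for {year}-{month:02d}")
        days = calendar.monthrange(year, month)[1]
        block = stack.values[sel]
        n_valid = np.isfinite(block).sum(axis=0)
        total = np.nansum(block, axis=0)
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
        layers.append(mean * (days / stack.composite_days))
    return np.stack(layers)


def compute_dhi(
    monthly_by_year: dict[int, np.ndarray],
    resolution_km: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DHIRaster:
    """Compute per-pixel DHI from per-year 12-layer monthly rasters.

    Per year: sum, minimum and CV (sample sd over mean; 0 where the mean is
    0) of the 12 monthly values; the final raster is the plain mean across
    years of each yearly index.
    """
    if not monthly_by_year:
        raise ValueError("need at least one year")
    sums, mins, cvs = [], [], []
    for year, monthly in sorted(monthly_by_year.items()):
        monthly = np.asarray(monthly, dtype=float)
        if monthly.shape[0] != 12:
            raise ValueError(f"year {year} must have 12 monthly layers")
        total = monthly.sum(axis=0)
        minimum = monthly.min(axis=0)
        mean = total / 12.0
        sd = monthly.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / mean, 0.0)
        cv = np.where(np.isnan(total), np.nan, cv)
        sums.append(total)
        mins.append(minimum)
        cvs.append(cv)
    return DHIRaster(
        sum=np.mean(sums, axis=0),
        minimum=np.mean(mins, axis=0),
        seasonality=np.mean(cvs, axis=0),
        resolution_km=resolution_km,
        origin=origin,
    )


def compute_dhi_from_stack(
    stack: ProductivityStack, years: list[int] | None = None
) -> DHIRaster:
    """Monthly aggregation plus DHI computation for every requested year."""
    years = years if years is not None else stack.years()
    monthly = {y: aggregate_to_monthly(stack, y) for y in years}
    return compute_dhi(monthly, stack.resolution_km, stack.origin)


def aggregate_pixels(grid: RasterGrid, factor: int) -> RasterGrid:
    """Block-average a single-band raster by an integer factor.

    Each coarse cell is the mean of its ``factor x factor`` fine cells,
    ignoring nodata; an all-nodata block stays nodata.  Edge blocks smaller
    than ``factor`` are averaged over the cells available.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return RasterGrid(grid.values.copy(), grid.resolution_km, grid.origin)
    v = grid.values
    if v.ndim != 2:
        raise ValueError("aggregate_pixels expects a single-band raster")
    rows = int(np.ceil(v.shape[0] / factor))
    cols = int(np.ceil(v.shape[1] / factor))
    out = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            block = v[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            if np.isfinite(block).any():
                out[i, j] = np.nanmean(block)
    return RasterGrid(out, grid.resolution_km * factor, grid.origin)


def aggregate_majority(grid: RasterGrid, factor: int) -> RasterGrid:
    """Block-aggregate a categorical raster by majority class.

    Ties resolve to the smallest class code; all-nodata blocks stay nodata.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return RasterGrid(grid.values.copy(), grid.resolution_km, grid.origin)
    v = grid.values
    rows = int(np.ceil(v.shape[0] / factor))
    cols = int(np.ceil(v.shape[1] / factor))
    out = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            block = v[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            vals = block[np.isfinite(block)].astype(int)
            if vals.size:
                counts = np.bincount(vals)
                out[i, j] = np.argmax(counts)
    return RasterGrid(out, grid.resolution_km * factor, grid.origin)


def buffer_mean(
    grid: RasterGrid, point: tuple[float, float], radius_km: float
) -> float:
    """Mean raster value over pixels whose centers fall within ``radius_km``.

    Raises if no valid (non-nodata) pixel center lies in the buffer.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if grid.values.ndim != 2:
        raise ValueError("buffer_mean expects a single-band raster")
    xs, ys = grid.pixel_centers()
    px, py = point
    dx2 = (xs - px) ** 2
    dy2 = (ys - py) ** 2
    mask = dy2[:, None] + dx2[None, :] <= radius_km**2
    vals = grid.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no valid pixels within {radius_km} km of {point}")
    return float(vals.mean())


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Mean-center and scale to unit sample standard deviation.

    Returns ``(z, mean, sd)`` so new locations can be projected with the
    same transform.  Raises on fewer than two distinct values.
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v[np.isfinite(v)])) < 2:
        raise ValueError("standardize needs at least two distinct values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance")
    return (v - mean) / sd, mean, sd
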