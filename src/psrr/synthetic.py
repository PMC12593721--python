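"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study's three inputs — an intra-annual GPP raster
time series, a categorical land-cover mosaic with human-dominated classes,
and a table of survey routes with mean species richness — and generates
richness from the spatially-varying-coefficient model itself,

    S_i = alpha(s_i) + beta(s_i) * PM_i + eps_i,

with alpha and beta drawn from Matérn (nu = 1) Gaussian fields with known
hyperparameters, so parameter-recovery tests know the truth.

One global seed drives everything.  Sub-streams are split deterministically
with ``numpy.random.SeedSequence.spawn`` in a fixed order (routes, intercept
field, slope field, noise, GPP, land cover), so each stage is independently
reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .grids import ProductivityStack, RasterGrid, write_raster
from .spde import SMOOTHNESS_NU, matern_correlation

__all__ = [
    "FieldParams",
    "GPPParams",
    "HumanCoverParams",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_gaussian_field",
    "simulate_gpp_stack",
    "simulate_landcover",
    "simulate_routes_and_richness",
    "simulate_dataset",
    "HUMAN_CLASSES",
    "LANDCOVER_CLASSES",
]

#: Land-cover codes; 2-4 are the human-dominated classes used by the
#: route-retention filter (croplands, urban/built-up, cropland mosaics).
LANDCOVER_CLASSES = {
    0: "forest",
    1: "grassland",
    2: "cropland",
    3: "urban",
    4: "cropland_mosaic",
}
HUMAN_CLASSES = frozenset({2, 3, 4})


@dataclass(frozen=True)
class FieldParams:
    """Gaussian-field settings for a spatially varying coefficient surface."""

    mean_level: float
    range_km: float
    marginal_sd: float

    def __post_init__(self):
        if self.range_km <= 0:
            raise ValueError("range_km must be positive")
        if self.marginal_sd < 0:
            raise ValueError("marginal_sd must be non-negative")


@dataclass(frozen=True)
class GPPParams:
    """Seasonal GPP surface: ``max(0, g(x,y) * (base + amp*sin(2*pi*m/12)) + noise)``
    with a linear spatial gradient ``g(x,y) = 1 + gx*(x-xc)/Lx + gy*(y-yc)/Ly``
    (xc, yc the domain center; Lx, Ly its side lengths)."""

    base_mean: float = 0.4
    seasonal_amplitude: float = 0.3
    gradient_x: float = 0.8
    gradient_y: float = 0.3
    pixel_noise_sd: float = 0.02


@dataclass(frozen=True)
class HumanCoverParams:
    """Smooth human-dominance probability surface for the land-cover mosaic."""

    base_fraction: float = 0.2
    gradient_x: float = 0.3
    gradient_y: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with one global seed.

    Defaults mirror the real study's conditions where those are stated:
    richness averages in the mid-50s over a continental domain, the
    productivity covariate is standardized, and the slope field's spatial
    range is of order 1,500 km.
    """

    domain_extent: tuple[float, float, float, float] = (0.0, 4500.0, 0.0, 3000.0)
    n_routes: int = 500
    grid_resolution_km: float = 150.0
    n_months: int = 12
    n_years: int = 4
    intercept_field: FieldParams = FieldParams(56.0, 1500.0, 3.0)
    slope_field: FieldParams = FieldParams(1.0, 1500.0, 0.5)
    noise_sd: float = 1.0
    gpp: GPPParams = GPPParams()
    human_cover: HumanCoverParams = HumanCoverParams()
    truth_resolution_km: float | None = None
    seed: int = 0

    def __post_init__(self):
        x0, x1, y0, y1 = self.domain_extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("domain extent must be strictly positive in both axes")
        if self.n_routes < 3:
            raise ValueError("need at least 3 routes")
        if self.grid_resolution_km <= 0:
            raise ValueError("grid_resolution_km must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_months * self.n_years < 2:
            raise ValueError("need at least 2 composites")

    def rngs(self) -> dict[str, np.random.Generator]:
        streams = ["routes", "alpha", "beta", "noise", "gpp", "landcover"]
        children = np.random.SeedSequence(self.seed).spawn(len(streams))
        return {k: np.random.default_rng(s) for k, s in zip(streams, children)}

    def gradient_factor(self, x, y) -> np.ndarray:
        x0, x1, y0, y1 = self.domain_extent
        g = (
            1.0
            + self.gpp.gradient_x * (np.asarray(x) - (x0 + x1) / 2) / (x1 - x0)
            + self.gpp.gradient_y * (np.asarray(y) - (y0 + y1) / 2) / (y1 - y0)
        )
        return np.maximum(g, 0.0)

    def noiseless_monthly_gpp(self, x, y, month: int) -> np.ndarray:
        """Closed-form noise-free monthly GPP at coordinates ``(x, y)``."""
        seasonal = self.gpp.base_mean + self.gpp.seasonal_amplitude * np.sin(
            2.0 * np.pi * month / 12.0
        )
        return np.maximum(0.0, self.gradient_factor(x, y) * seasonal)


@dataclass
class SyntheticDataset:
    """A complete simulated study with its generating truth attached."""

    routes: "object"  # pandas.DataFrame
    gpp_stack: ProductivityStack | None
    landcover: RasterGrid | None
    truth: dict
    config: SimulationConfig


def simulate_gaussian_field(
    points: np.ndarray,
    range_km: float,
    marginal_sd: float,
    nu: float = SMOOTHNESS_NU,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw a zero-mean Gaussian field with Matérn correlation at ``points``.

    Coincident points receive identical values exactly.  A jitter ladder
    (1e-10 to 1e-6 times the marginal variance) guards the Cholesky
    factorization; if every level fails a ``LinAlgError`` reports the levels
    tried.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 1:
        raise ValueError("need at least one point")
    if marginal_sd < 0:
        raise ValueError("marginal_sd must be non-negative")
    if marginal_sd == 0:
        return np.zeros(len(pts))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    dist = cdist(uniq, uniq)
    corr = matern_correlation(dist, range_km, nu)
    var = marginal_sd**2
    z = rng.standard_normal(len(uniq))
    tried = []
    for jitter in (1e-10, 1e-8, 1e-6):
        tried.append(jitter)
        try:
            chol = np.linalg.cholesky(var * corr + var * jitter * np.eye(len(uniq)))
            return (chol @ z)[inverse]
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"covariance not positive definite after jitter levels {tried}"
    )


def simulate_gpp_stack(config: SimulationConfig) -> ProductivityStack:
    """Simulate a monthly GPP composite stack over the configured domain."""
    rng = config.rngs()["gpp"]
    x0, x1, y0, y1 = config.domain_extent
    res = config.grid_resolution_km
    n_cols = max(int(round((x1 - x0) / res)), 1)
    n_rows = max(int(round((y1 - y0) / res)), 1)
    xs = x0 + (np.arange(n_cols) + 0.5) * res
    ys = y0 + (np.arange(n_rows) + 0.5) * res
    xx, yy = np.meshgrid(xs, ys)
    layers, dates = [], []
    for year_idx in range(config.n_years):
        year = 2001 + year_idx
        for month in range(1, config.n_months + 1):
            clean = config.noiseless_monthly_gpp(xx, yy, month)
            noise = (
                rng.standard_normal(clean.shape) * config.gpp.pixel_noise_sd
                if config.gpp.pixel_noise_sd > 0
                else 0.0
            )
            layers.append(np.maximum(0.0, clean + noise))
            dates.append(_dt.date(year, month, 1))
    return ProductivityStack(
        values=np.stack(layers),
        composite_start_dates=dates,
        resolution_km=res,
        origin=(x0, y0),
        composite_days=30,
        monthly=True,
    )


def simulate_landcover(config: SimulationConfig) -> RasterGrid:
    """Simulate a categorical land-cover mosaic with human-dominated classes."""
    rng = config.rngs()["landcover"]
    x0, x1, y0, y1 = config.domain_extent
    res = config.grid_resolution_km
    n_cols = max(int(round((x1 - x0) / res)), 1)
    n_rows = max(int(round((y1 - y0) / res)), 1)
    xs = x0 + (np.arange(n_cols) + 0.5) * res
    ys = y0 + (np.arange(n_rows) + 0.5) * res
    xx, yy = np.meshgrid(xs, ys)
    hc = config.human_cover
    p_human = np.clip(
        hc.base_fraction
        + hc.gradient_x * (xx - (x0 + x1) / 2) / (x1 - x0)
        + hc.gradient_y * (yy - (y0 + y1) / 2) / (y1 - y0),
        0.0,
        1.0,
    )
    human = rng.random(p_human.shape) < p_human
    human_codes = rng.choice(sorted(HUMAN_CLASSES), size=p_human.shape)
    natural_codes = rng.choice([0, 1], size=p_human.shape)
    codes = np.where(human, human_codes, natural_codes).astype(float)
    return RasterGrid(codes, res, (x0, y0))


def _truth_grid(config: SimulationConfig) -> tuple[np.ndarray, tuple[int, int], float]:
    x0, x1, y0, y1 = config.domain_extent
    res = config.truth_resolution_km or max(
        config.grid_resolution_km, max(x1 - x0, y1 - y0) / 25.0
    )
    xs = x0 + (np.arange(max(int(round((x1 - x0) / res)), 1)) + 0.5) * res
    ys = y0 + (np.arange(max(int(round((y1 - y0) / res)), 1)) + 0.5) * res
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()]), xx.shape, res


def simulate_routes_and_richness(
    config: SimulationConfig,
    pm_values: np.ndarray | None = None,
    locations: np.ndarray | None = None,
) -> SyntheticDataset:
    """Draw route locations and generate richness from the SVC model.

    ``pm_values`` is the standardized productivity covariate, one value per
    route; if omitted, an i.i.d. standard-normal covariate is drawn and
    standardized.  The truth surfaces (one joint Gaussian draw over routes
    plus a regular truth grid) are stored in ``dataset.truth``.
    """
    import pandas as pd

    rngs = config.rngs()
    x0, x1, y0, y1 = config.domain_extent
    if locations is None:
        locations = np.column_stack(
            [
                rngs["routes"].uniform(x0, x1, config.n_routes),
                rngs["routes"].uniform(y0, y1, config.n_routes),
            ]
        )
    else:
        locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n = len(locations)
    if pm_values is None:
        pm = rngs["routes"].standard_normal(n)
        pm = (pm - pm.mean()) / pm.std(ddof=1)
    else:
        pm = np.asarray(pm_values, dtype=float)
        if pm.shape != (n,):
            raise ValueError("pm_values must supply one value per route")
        if not np.all(np.isfinite(pm)):
            raise ValueError("pm_values must be finite")

    grid_pts, grid_shape, grid_res = _truth_grid(config)
    all_pts = np.vstack([locations, grid_pts])
    icf, scf = config.intercept_field, config.slope_field
    alpha = icf.mean_level + simulate_gaussian_field(
        all_pts, icf.range_km, icf.marginal_sd, rng=rngs["alpha"]
    )
    beta = scf.mean_level + simulate_gaussian_field(
        all_pts, scf.range_km, scf.marginal_sd, rng=rngs["beta"]
    )
    eps = rngs["noise"].standard_normal(n) * config.noise_sd
    richness = alpha[:n] + beta[:n] * pm + eps

    routes = pd.DataFrame(
        {
            "route_id": np.arange(1, n + 1),
            "x_km": locations[:, 0],
            "y_km": locations[:, 1],
            "richness": richness,
            "pm_std": pm,
        }
    )
    truth = {
        "alpha_routes": alpha[:n],
        "beta_routes": beta[:n],
        "alpha_surface": RasterGrid(
            alpha[n:].reshape(grid_shape), grid_res, (x0, y0)
        ),
        "beta_surface": RasterGrid(beta[n:].reshape(grid_shape), grid_res, (x0, y0)),
        "hyperparameters": {
            "intercept": asdict(icf),
            "slope": asdict(scf),
            "noise_sd": config.noise_sd,
            "nu": SMOOTHNESS_NU,
        },
    }
    return SyntheticDataset(
        routes=routes, gpp_stack=None, landcover=None, truth=truth, config=config
    )


def simulate_dataset(
    config: SimulationConfig,
    measure: str = "sum",
    radius_km: float | None = None,
) -> SyntheticDataset:
    """Simulate the full study: GPP stack, land cover, routes and richness.

    The productivity covariate is computed from the simulated stack the same
    way the analysis pipeline computes it (monthly DHI, averaged over years,
    buffer means around route start points, standardization), so the dataset
    is end-to-end self-consistent.  ``radius_km`` defaults to a quarter of
    the shorter domain side, capped at the study's 39.4 km where the grid is
    fine enough to resolve it.
    """
    from .productivity import buffer_mean, compute_dhi_from_stack, standardize

    stack = simulate_gpp_stack(config)
    landcover = simulate_landcover(config)
    dhi = compute_dhi_from_stack(stack)
    band = dhi.band(measure if measure != "min" else "minimum")

    rngs = config.rngs()
    x0, x1, y0, y1 = config.domain_extent
    if radius_km is None:
        radius_km = min(39.4, 0.25 * min(x1 - x0, y1 - y0))
    # Keep buffers inside the domain so every buffer has valid pixels.
    locations = np.column_stack(
        [
            rngs["routes"].uniform(x0 + radius_km, x1 - radius_km, config.n_routes),
            rngs["routes"].uniform(y0 + radius_km, y1 - radius_km, config.n_routes),
        ]
    )
    pm_raw = np.array(
        [buffer_mean(band, (x, y), max(radius_km, band.resolution_km)) for x, y in locations]
    )
    pm_std, _, _ = standardize(pm_raw)
    ds = simulate_routes_and_richness(config, pm_values=pm_std, locations=locations)
    ds.routes["pm_raw"] = pm_raw
    ds.gpp_stack = stack
    ds.landcover = landcover
    return ds


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Persist a synthetic dataset (routes CSV, rasters, truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.routes.to_csv(out / "routes.csv", index=False)
    if ds.gpp_stack is not None:
        grid = RasterGrid(
            ds.gpp_stack.values, ds.gpp_stack.resolution_km, ds.gpp_stack.origin
        )
        write_raster(
            out / "gpp_stack.txt",
            grid,
            band_names=[d.isoformat() for d in ds.gpp_stack.composite_start_dates],
        )
    if ds.landcover is not None:
        write_raster(out / "landcover.txt", ds.landcover)
    truth = {
        "hyperparameters": ds.truth["hyperparameters"],
        "config": asdict(ds.config),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    write_raster(out / "truth_alpha.txt", ds.truth["alpha_surface"])
    write_raster(out / "truth_beta.txt", ds.truth["beta_surface"])
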