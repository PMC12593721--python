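import datetime as dt

import numpy as np
import pandas as pd
import pytest

import psrr


@pytest.fixture(scope="session")
def small_mesh_points():
    rng = np.random.default_rng(7)
    return rng.uniform(0, 1000, size=(40, 2))


@pytest.fixture(scope="session")
def small_mesh(small_mesh_points):
    return psrr.build_mesh(small_mesh_points, max_edge_km=120.0, hull_buffer_km=200.0)


@pytest.fixture(scope="session")
def quick_fit():
    """A small but genuine SVC fit shared by structural tests.

    80 routes over a 2,000-km square, mild spatial signal, short chain;
    adequate for testing interfaces, summaries, prediction and diagnostics
    (not for posterior quality).
    """
    cfg = psrr.SimulationConfig(
        domain_extent=(0.0, 2000.0, 0.0, 2000.0),
        n_routes=80,
        intercept_field=psrr.FieldParams(50.0, 800.0, 2.0),
        slope_field=psrr.FieldParams(1.5, 800.0, 0.5),
        noise_sd=1.0,
        seed=5,
    )
    ds = psrr.simulate_routes_and_richness(cfg)
    pts = ds.routes[["x_km", "y_km"]].to_numpy()
    mesh = psrr.build_mesh(pts, max_edge_km=300.0)
    priors = psrr.PriorConfig.with_range_threshold(1000.0)
    inf = psrr.InferenceConfig(seed=21, n_iter=600, n_burn=200, thin=4, n_latent_draws=60)
    fit = psrr.fit_svc(ds.routes, mesh, priors, inf)
    return ds, fit


def monthly_stack(values_by_month, resolution_km=1.0, year=2001):
    """Build a monthly ProductivityStack from a (12, r, c) array."""
    values = np.asarray(values_by_month, dtype=float)
    dates = [dt.date(year, m, 1) for m in range(1, values.shape[0] + 1)]
    return psrr.ProductivityStack(
        values=values,
        composite_start_dates=dates,
        resolution_km=resolution_km,
        composite_days=30,
        monthly=True,
    )
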