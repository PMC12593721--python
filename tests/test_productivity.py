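"""Dynamic habitat indices: monthly aggregation, DHI arithmetic, buffers."""

import datetime as dt

import numpy as np
import pytest

import psrr
from conftest import monthly_stack
from psrr.grids import ProductivityStack, RasterGrid


def eight_day_stack(values, dates, resolution_km=1.0):
    return ProductivityStack(
        values=np.asarray(values, dtype=float),
        composite_start_dates=dates,
        resolution_km=resolution_km,
        composite_days=8,
    )


class TestMonthlyAggregation:
    def test_june_composites_scale_to_monthly_total(self):
        """Four 8-day composites of 0.1 in a 30-day month give 0.1*(30/8)."""
        dates = [dt.date(2001, 6, d) for d in (1, 9, 17, 25)] + [
            dt.date(2001, m, 1) for m in list(range(1, 6)) + list(range(7, 13))
        ]
        values = np.full((len(dates), 2, 2), 0.1)
        monthly = psrr.aggregate_to_monthly(eight_day_stack(values, dates), 2001)
        assert monthly[5, 0, 0] == pytest.approx(0.1 * 30 / 8)

    def test_all_nodata_pixel_propagates(self):
        dates = [dt.date(2001, m, 1) for m in range(1, 13)]
        values = np.full((12, 1, 1), 0.2)
        values[:, 0, 0] = np.nan
        monthly = psrr.aggregate_to_monthly(eight_day_stack(values, dates), 2001)
        assert np.isnan(monthly).all()

    def test_monthly_stack_passthrough(self):
        vals = np.arange(12, dtype=float).reshape(12, 1, 1) + 1
        stack = monthly_stack(vals)
        monthly = psrr.aggregate_to_monthly(stack, 2001)
        np.testing.assert_array_equal(monthly, vals)

    def test_missing_month_names_the_month(self):
        dates = [dt.date(2001, m, 1) for m in range(1, 12)]  # no December
        values = np.full((11, 1, 1), 0.1)
        with pytest.raises(ValueError, match="2001-12"):
            psrr.aggregate_to_monthly(eight_day_stack(values, dates), 2001)


class TestComputeDHI:
    def test_one_through_twelve_worked_example(self):
        """Months 1..12: sum 78, min 1, CV = sd(1..12)/6.5 with sample sd."""
        monthly = np.arange(1, 13, dtype=float).reshape(12, 1, 1)
        dhi = psrr.compute_dhi({2001: monthly}, resolution_km=1.0)
        assert dhi.sum[0, 0] == pytest.approx(78.0)
        assert dhi.minimum[0, 0] == pytest.approx(1.0)
        assert dhi.seasonality[0, 0] == pytest.approx(3.605551275463989 / 6.5, abs=1e-12)

    def test_constant_and_zero_pixels(self):
        monthly = np.zeros((12, 1, 2))
        monthly[:, 0, 0] = 0.5
        dhi = psrr.compute_dhi({2001: monthly}, resolution_km=1.0)
        assert dhi.sum[0, 0] == pytest.approx(6.0)
        assert dhi.minimum[0, 0] == pytest.approx(0.5)
        assert dhi.seasonality[0, 0] == 0.0
        # all-zero pixel: seasonality defined as 0, not NaN
        assert dhi.sum[0, 1] == 0.0
        assert dhi.seasonality[0, 1] == 0.0

    def test_multi_year_plain_average(self):
        y1 = np.full((12, 1, 1), 1.0)
        y2 = np.full((12, 1, 1), 3.0)
        dhi = psrr.compute_dhi({2001: y1, 2002: y2}, resolution_km=1.0)
        assert dhi.sum[0, 0] == pytest.approx((12.0 + 36.0) / 2)
        assert dhi.minimum[0, 0] == pytest.approx(2.0)

    def test_noiseless_sinusoid_matches_closed_form(self):
        """DHI of a simulated noise-free seasonal stack to 1e-9."""
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 300, 0, 200), n_routes=3,
            grid_resolution_km=50.0, n_years=2,
            gpp=psrr.GPPParams(base_mean=0.4, seasonal_amplitude=0.3,
                               gradient_x=0.8, gradient_y=0.4, pixel_noise_sd=0.0),
            seed=0,
        )
        stack = psrr.simulate_gpp_stack(cfg)
        dhi = psrr.compute_dhi_from_stack(stack)
        xs, ys = stack.grid.pixel_centers()
        xx, yy = np.meshgrid(xs, ys)
        months = np.arange(1, 13)
        series = np.stack([cfg.noiseless_monthly_gpp(xx, yy, m) for m in months])
        np.testing.assert_allclose(dhi.sum, series.sum(axis=0), atol=1e-9)
        np.testing.assert_allclose(dhi.minimum, series.min(axis=0), atol=1e-9)
        mean = series.mean(axis=0)
        cv = np.where(mean != 0, series.std(axis=0, ddof=1) / np.where(mean != 0, mean, 1), 0)
        np.testing.assert_allclose(dhi.seasonality, cv, atol=1e-9)


class TestAggregatePixels:
    def test_factor_one_identity(self):
        g = RasterGrid(np.arange(4.0).reshape(2, 2), 1.0)
        out = psrr.aggregate_pixels(g, 1)
        np.testing.assert_array_equal(out.values, g.values)

    def test_block_mean_and_nodata(self):
        g = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 1.0)
        assert psrr.aggregate_pixels(g, 2).values[0, 0] == pytest.approx(2.5)
        g2 = RasterGrid(np.array([[1.0, np.nan], [3.0, np.nan]]), 1.0)
        assert psrr.aggregate_pixels(g2, 2).values[0, 0] == pytest.approx(2.0)
        g3 = RasterGrid(np.full((2, 2), np.nan), 1.0)
        assert np.isnan(psrr.aggregate_pixels(g3, 2).values[0, 0])

    def test_edge_blocks_use_available_cells(self):
        g = RasterGrid(np.arange(9.0).reshape(3, 3), 1.0)
        out = psrr.aggregate_pixels(g, 2)
        assert out.values.shape == (2, 2)
        assert out.values[1, 1] == pytest.approx(8.0)  # single corner cell

    def test_majority_aggregation_ties_to_smallest_code(self):
        g = RasterGrid(np.array([[0.0, 1.0], [1.0, 0.0]]), 1.0)
        assert psrr.aggregate_majority(g, 2).values[0, 0] == 0.0


class TestBufferMean:
    def test_constant_raster(self):
        g = RasterGrid(np.full((10, 10), 3.7), 1.0)
        assert psrr.buffer_mean(g, (5.0, 5.0), 3.0) == pytest.approx(3.7)

    def test_tiny_radius_returns_center_pixel(self):
        g = RasterGrid(np.arange(25.0).reshape(5, 5), 1.0)
        assert psrr.buffer_mean(g, (2.5, 2.5), 0.3) == pytest.approx(g.values[2, 2])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        g = RasterGrid(rng.random((20, 20)), 1.0)
        point, radius = (9.3, 11.1), 5.2
        acc = []
        for i in range(20):
            for j in range(20):
                x, y = (j + 0.5) * 1.0, (i + 0.5) * 1.0
                if (x - point[0]) ** 2 + (y - point[1]) ** 2 <= radius**2:
                    acc.append(g.values[i, j])
        assert psrr.buffer_mean(g, point, radius) == pytest.approx(np.mean(acc), abs=0)

    def test_linear_ramp_symmetric_buffer(self):
        vals = np.tile(np.arange(30.0), (30, 1))
        g = RasterGrid(vals, 1.0)
        got = psrr.buffer_mean(g, (15.0, 15.0), 6.0)
        assert got == pytest.approx(14.5, abs=1.0)  # ramp value at center

    def test_empty_buffer_errors(self):
        g = RasterGrid(np.full((5, 5), np.nan), 1.0)
        with pytest.raises(ValueError, match="no valid pixels"):
            psrr.buffer_mean(g, (2.5, 2.5), 1.0)

    def test_aggregate_then_buffer_consistent_for_smooth_field(self):
        xx, yy = np.meshgrid(np.arange(40) + 0.5, np.arange(40) + 0.5)
        g = RasterGrid(0.1 * xx + 0.05 * yy, 1.0)
        coarse = psrr.aggregate_pixels(g, 2)
        fine_val = psrr.buffer_mean(g, (20.0, 20.0), 10.0)
        coarse_val = psrr.buffer_mean(coarse, (20.0, 20.0), 10.0)
        assert coarse_val == pytest.approx(fine_val, abs=0.15)


class TestStandardize:
    def test_arithmetic_and_idempotence(self):
        z, mean, sd = psrr.standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-12)
        assert (mean, sd) == (2.0, 1.0)
        z2, _, _ = psrr.standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        z, _, _ = psrr.standardize(rng.random(100) * 7 + 3)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            psrr.standardize([2.0, 2.0, 2.0])
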