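"""Generator correctness: Gaussian-field draws, GPP stacks, SVC-model richness."""

import numpy as np
import pytest

import psrr
from psrr.spde import matern_correlation


class TestGaussianField:
    def test_zero_sd_gives_exact_zeros(self):
        vals = psrr.simulate_gaussian_field([(3.0, 4.0)], 10.0, 0.0, rng=0)
        assert vals == pytest.approx([0.0], abs=0)

    def test_coincident_points_get_identical_values(self):
        pts = [(1.0, 2.0), (1.0, 2.0), (5.0, 5.0)]
        vals = psrr.simulate_gaussian_field(pts, 10.0, 1.0, rng=1)
        assert vals[0] == vals[1]
        assert vals[0] != vals[2]

    def test_monte_carlo_correlation_matches_closed_form(self):
        """Pairs one range apart decorrelate to the Matern level (~0.13)."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        draws = np.array(
            [
                psrr.simulate_gaussian_field(pts, 1.0, 1.0, rng=np.random.default_rng(s))
                for s in range(2000)
            ]
        )
        emp = np.corrcoef(draws.T)[0, 1]
        assert emp == pytest.approx(matern_correlation(1.0, 1.0), abs=0.05)

    def test_variogram_sill_matches_marginal_variance(self):
        """The empirical variogram flattens near the marginal variance."""
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 2000, size=(1000, 2))
        field = psrr.simulate_gaussian_field(pts, 300.0, 2.0, rng=rng)
        v = psrr.empirical_variogram(pts, field, n_bins=10, max_lag=1000.0)
        sill = np.nanmean(v.semivariance[v.bin_centers > 300.0])
        assert sill == pytest.approx(4.0, rel=0.2)


class TestGPPStack:
    def test_constant_series_closed_form(self):
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 100, 0, 100),
            n_routes=3,
            grid_resolution_km=25.0,
            n_years=1,
            gpp=psrr.GPPParams(
                base_mean=0.5, seasonal_amplitude=0.0,
                gradient_x=0.0, gradient_y=0.0, pixel_noise_sd=0.0,
            ),
            seed=0,
        )
        stack = psrr.simulate_gpp_stack(cfg)
        dhi = psrr.compute_dhi_from_stack(stack)
        assert np.allclose(dhi.sum, 6.0)
        assert np.allclose(dhi.minimum, 0.5)
        assert np.allclose(dhi.seasonality, 0.0)

    def test_noiseless_min_is_clipped_sinusoid_low(self):
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 100, 0, 100),
            n_routes=3,
            grid_resolution_km=50.0,
            n_years=1,
            gpp=psrr.GPPParams(
                base_mean=0.4, seasonal_amplitude=0.6,
                gradient_x=0.0, gradient_y=0.0, pixel_noise_sd=0.0,
            ),
            seed=0,
        )
        stack = psrr.simulate_gpp_stack(cfg)
        # Evaluate the stored sinusoid on the month grid; the floor is 0.
        months = np.arange(1, 13)
        series = np.maximum(0.0, 0.4 + 0.6 * np.sin(2 * np.pi * months / 12))
        assert np.allclose(stack.values.min(axis=0), series.min())

    def test_same_seed_identical_stacks(self):
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 200, 0, 200), n_routes=3,
            grid_resolution_km=50.0, n_years=2, seed=42,
        )
        s1 = psrr.simulate_gpp_stack(cfg)
        s2 = psrr.simulate_gpp_stack(cfg)
        np.testing.assert_array_equal(s1.values, s2.values)


class TestRoutesAndRichness:
    def test_pure_intercept_surface(self):
        """With no slope and no noise, richness equals the intercept field."""
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 500, 0, 500), n_routes=20,
            intercept_field=psrr.FieldParams(40.0, 200.0, 2.0),
            slope_field=psrr.FieldParams(0.0, 200.0, 0.0),
            noise_sd=0.0, seed=9,
        )
        ds = psrr.simulate_routes_and_richness(cfg, pm_values=np.linspace(-1, 1, 20))
        np.testing.assert_allclose(
            ds.routes["richness"], ds.truth["alpha_routes"], atol=1e-12
        )

    def test_deterministic_linear_model(self):
        """alpha=50, beta=2, PM=1.5 everywhere gives richness 53 exactly."""
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 500, 0, 500), n_routes=10,
            intercept_field=psrr.FieldParams(50.0, 200.0, 0.0),
            slope_field=psrr.FieldParams(2.0, 200.0, 0.0),
            noise_sd=0.0, seed=2,
        )
        ds = psrr.simulate_routes_and_richness(cfg, pm_values=np.full(10, 1.5))
        np.testing.assert_allclose(ds.routes["richness"], 53.0, atol=1e-12)

    def test_seeded_reproducibility(self):
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 1000, 0, 1000), n_routes=50, seed=33
        )
        d1 = psrr.simulate_routes_and_richness(cfg)
        d2 = psrr.simulate_routes_and_richness(cfg)
        np.testing.assert_array_equal(d1.routes["richness"], d2.routes["richness"])
        np.testing.assert_array_equal(
            d1.truth["beta_surface"].values, d2.truth["beta_surface"].values
        )

    def test_truth_defined_at_routes_and_grid(self):
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 1000, 0, 1000), n_routes=40, seed=4
        )
        ds = psrr.simulate_routes_and_richness(cfg)
        assert np.all(np.isfinite(ds.truth["alpha_routes"]))
        assert np.all(np.isfinite(ds.truth["beta_surface"].values))

    def test_residual_noise_law_of_large_numbers(self):
        """Richness minus the truth signal behaves like the configured noise."""
        n = 5000
        noise_sd = 2.0
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 3000, 0, 3000), n_routes=n,
            intercept_field=psrr.FieldParams(50.0, 500.0, 0.0),
            slope_field=psrr.FieldParams(1.0, 500.0, 0.0),
            noise_sd=noise_sd, seed=12,
        )
        ds = psrr.simulate_routes_and_richness(cfg)
        signal = ds.truth["alpha_routes"] + ds.truth["beta_routes"] * ds.routes["pm_std"]
        resid = ds.routes["richness"].to_numpy() - signal
        se_mean = noise_sd / np.sqrt(n)
        se_sd = noise_sd / np.sqrt(2 * n)
        assert abs(resid.mean()) < 3 * se_mean
        assert abs(resid.std(ddof=1) - noise_sd) < 3 * se_sd


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(domain_extent=(10, 10, 0, 5)),
            dict(n_routes=2),
            dict(grid_resolution_km=0.0),
            dict(noise_sd=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            psrr.SimulationConfig(**kwargs)

    def test_dataset_roundtrip_write(self, tmp_path):
        cfg = psrr.SimulationConfig(
            domain_extent=(0, 400, 0, 400), n_routes=10,
            grid_resolution_km=50.0, n_years=1, seed=8,
        )
        ds = psrr.simulate_dataset(cfg)
        from psrr.synthetic import write_dataset

        write_dataset(ds, tmp_path)
        assert (tmp_path / "routes.csv").exists()
        lc = psrr.read_raster(tmp_path / "landcover.txt")
        np.testing.assert_array_equal(lc.values, ds.landcover.values)
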