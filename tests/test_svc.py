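"""SVC inference: likelihood oracle, degenerate limits, prediction, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import psrr
from psrr.spde import matern_correlation
from psrr.svc import effective_sample_size, empirical_variogram


def dense_gp_loglik(routes, hp, fixed_effect_prec=1e-6):
    """Independent oracle: marginal likelihood via a dense Matérn GP.

    Integrates the two Gaussian coefficient surfaces and the vague fixed
    effects analytically in covariance form, with no mesh or sparse algebra.
    """
    pts = routes[["x_km", "y_km"]].to_numpy()
    pm = routes["pm_std"].to_numpy()
    y = routes["richness"].to_numpy()
    n = len(y)
    d = cdist(pts, pts)
    ka = hp["sd_alpha"] ** 2 * matern_correlation(d, hp["range_alpha"])
    kb = hp["sd_beta"] ** 2 * matern_correlation(d, hp["range_beta"])
    x = np.column_stack([np.ones(n), pm])
    sigma = (
        ka
        + np.outer(pm, pm) * kb
        + np.eye(n) / hp["noise_precision"]
        + x @ x.T / fixed_effect_prec
    )
    chol = np.linalg.cholesky(sigma)
    w = np.linalg.solve(chol, y)
    return float(
        -0.5 * w @ w - np.log(np.diag(chol)).sum() - 0.5 * n * np.log(2 * np.pi)
    )


def simulate_gp_routes(n, domain, hp, mean_alpha, mean_beta, seed):
    """Data drawn exactly from the SVC model with dense Matérn fields."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, domain, size=(n, 2))
    pm = rng.standard_normal(n)
    pm = (pm - pm.mean()) / pm.std(ddof=1)
    d = cdist(pts, pts)
    jit = 1e-9 * np.eye(n)
    a = mean_alpha + hp["sd_alpha"] * np.linalg.cholesky(
        matern_correlation(d, hp["range_alpha"]) + jit
    ) @ rng.standard_normal(n)
    b = mean_beta + hp["sd_beta"] * np.linalg.cholesky(
        matern_correlation(d, hp["range_beta"]) + jit
    ) @ rng.standard_normal(n)
    y = a + b * pm + rng.standard_normal(n) / np.sqrt(hp["noise_precision"])
    return pd.DataFrame(
        dict(x_km=pts[:, 0], y_km=pts[:, 1], richness=y, pm_std=pm)
    )


class TestMarginalLikelihoodOracle:
    def test_gmrf_path_matches_dense_gp(self):
        """SPDE-GMRF and dense-GP marginal log-likelihoods agree closely."""
        hp = dict(
            range_alpha=3.0, sd_alpha=2.0, range_beta=3.0, sd_beta=1.0,
            noise_precision=4.0,
        )
        routes = simulate_gp_routes(60, 10.0, hp, 50.0, 1.0, seed=1)
        pts = routes[["x_km", "y_km"]].to_numpy()
        mesh = psrr.build_mesh(pts, max_edge_km=0.6, hull_buffer_km=3.0)
        ll = psrr.gmrf_marginal_loglik(routes, mesh, hp)
        ll_oracle = dense_gp_loglik(routes, hp)
        assert abs(ll - ll_oracle) / abs(ll_oracle) < 0.02


class TestFitStructure:
    def test_requires_standardized_covariate(self, quick_fit):
        ds, _ = quick_fit
        bad = ds.routes.copy()
        bad["pm_std"] = bad["pm_std"] * 5 + 2
        mesh = psrr.build_mesh(bad[["x_km", "y_km"]].to_numpy(), 500.0)
        with pytest.raises(ValueError, match="standardized"):
            psrr.fit_svc(
                bad, mesh, psrr.PriorConfig(), psrr.InferenceConfig(seed=0, n_iter=10)
            )

    def test_requires_minimum_routes(self):
        routes = pd.DataFrame(
            dict(x_km=[0.0, 1.0], y_km=[0.0, 1.0], richness=[1.0, 2.0],
                 pm_std=[-0.7, 0.7])
        )
        with pytest.raises(ValueError, match="at least 30"):
            psrr.fit_svc(
                routes, None, psrr.PriorConfig(), psrr.InferenceConfig(seed=0)
            )

    def test_range_summary_quantiles_ordered(self, quick_fit):
        _, fit = quick_fit
        for field in ("alpha", "beta"):
            med, lo, hi = psrr.posterior_range_summary(fit, field)
            assert lo <= med <= hi

    def test_degenerate_posterior_summary(self, quick_fit):
        _, fit = quick_fit
        frozen = fit.hyper_draws.copy()
        fit2 = fit
        fit2.hyper_draws = frozen.assign(range_beta=1234.5)
        med, lo, hi = psrr.posterior_range_summary(fit2, "beta")
        assert med == lo == hi == 1234.5
        fit2.hyper_draws = frozen

    def test_same_seed_reproduces_fit_bit_exactly(self):
        hp = dict(range_alpha=800.0, sd_alpha=2.0, range_beta=800.0,
                  sd_beta=0.5, noise_precision=1.0)
        routes = simulate_gp_routes(60, 2000.0, hp, 50.0, 1.0, seed=3)
        mesh = psrr.build_mesh(routes[["x_km", "y_km"]].to_numpy(), 400.0)
        cfg = psrr.InferenceConfig(seed=9, n_iter=200, n_burn=80, thin=4,
                                   n_latent_draws=20)
        f1 = psrr.fit_svc(routes, mesh, psrr.PriorConfig(), cfg)
        f2 = psrr.fit_svc(routes, mesh, psrr.PriorConfig(), cfg)
        pd.testing.assert_frame_equal(f1.hyper_draws, f2.hyper_draws)
        np.testing.assert_array_equal(f1.latent_draws, f2.latent_draws)


class TestPrediction:
    def test_vertex_prediction_equals_vertex_posterior(self, quick_fit):
        _, fit = quick_fit
        idx = fit.mesh.n_vertices // 2
        v = fit.mesh.vertices[idx]
        pred = psrr.predict_coefficients(fit, [v])
        m = fit.mesh.n_vertices
        beta_vertex = fit.latent_draws[:, 1] + fit.latent_draws[:, 2 + m + idx]
        assert pred["beta_median"].iloc[0] == pytest.approx(
            np.median(beta_vertex), abs=1e-9
        )

    def test_draws_inside_convex_hull_of_vertex_draws(self, quick_fit):
        _, fit = quick_fit
        tri = fit.mesh.triangles[0]
        centroid = fit.mesh.vertices[tri].mean(axis=0)
        a_loc = fit.mesh.projector([centroid])
        alpha, _ = fit.coefficient_draws(a_loc)
        m = fit.mesh.n_vertices
        vert_draws = fit.latent_draws[:, 0][:, None] + fit.latent_draws[:, 2 + tri]
        assert np.all(alpha[:, 0] <= vert_draws.max(axis=1) + 1e-9)
        assert np.all(alpha[:, 0] >= vert_draws.min(axis=1) - 1e-9)

    def test_quantile_ordering_pointwise(self, quick_fit):
        ds, fit = quick_fit
        rng = np.random.default_rng(0)
        pts = rng.uniform(400, 1600, size=(40, 2))
        pred = psrr.predict_coefficients(fit, pts)
        assert (pred["beta_q025"] <= pred["beta_median"]).all()
        assert (pred["beta_median"] <= pred["beta_q975"]).all()

    def test_outside_mesh_raises(self, quick_fit):
        _, fit = quick_fit
        with pytest.raises(ValueError, match="outside"):
            psrr.predict_coefficients(fit, [(1e7, 1e7)])


class TestResidualDiagnostics:
    def test_exact_fit_gives_zero_residuals(self, quick_fit):
        """If the latent draws reproduce the data, residuals vanish."""
        ds, fit = quick_fit
        import copy

        exact = copy.copy(fit)
        a, b = 47.0, 1.3
        routes = fit.routes.copy()
        routes[fit.response] = a + b * routes[fit.covariate]
        exact.routes = routes
        latent = np.zeros((5, 2 * fit.mesh.n_vertices + 2))
        latent[:, 0] = a
        latent[:, 1] = b
        exact.latent_draws = latent
        residuals, fitted, _ = psrr.residual_diagnostics(exact, n_permutations=0)
        assert np.abs(residuals).max() < 1e-9

    def test_pure_noise_variogram_stays_in_envelope(self):
        """White-noise residual variograms sit inside the permutation band."""
        rng = np.random.default_rng(10)
        inside = total = 0
        for rep in range(10):
            pts = rng.uniform(0, 1000, size=(120, 2))
            vals = rng.standard_normal(120)
            v = empirical_variogram(
                pts, vals, n_bins=8, n_permutations=99, rng=rng
            )
            inside += np.sum(
                (v.semivariance >= v.envelope_low)
                & (v.semivariance <= v.envelope_high)
            )
            total += len(v.semivariance)
        # pointwise 95% band: ~95% of bins should fall inside under the null
        assert inside / total >= 0.90

    def test_bin_counts_account_for_all_pairs(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, size=(50, 2))
        vals = rng.standard_normal(50)
        max_lag = 60.0
        v = empirical_variogram(pts, vals, n_bins=6, max_lag=max_lag)
        d = cdist(pts, pts)[np.triu_indices(50, 1)]
        assert v.counts.sum() == (d < max_lag).sum()

    def test_fit_diagnostics_run_end_to_end(self, quick_fit):
        _, fit = quick_fit
        residuals, fitted, vario = psrr.residual_diagnostics(fit, n_permutations=19)
        assert len(residuals) == len(fit.routes)
        assert vario.envelope_low is not None


def test_effective_sample_size_sane():
    rng = np.random.default_rng(0)
    iid = rng.standard_normal(500)
    assert effective_sample_size(iid) > 250
    # heavily autocorrelated chain has far lower ESS
    ar = np.zeros(500)
    for i in range(1, 500):
        ar[i] = 0.95 * ar[i - 1] + rng.standard_normal() * 0.1
    assert effective_sample_size(ar) < 120
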