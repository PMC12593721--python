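"""Bayesian inference for the spatially varying coefficient (SVC) model.

The model for mean species richness S_i at route location s_i with
standardized productivity covariate PM_i is

    S_i = alpha(s_i) + beta(s_i) * PM_i + eps_i,
    eps_i ~ Normal(0, 1 / tau_eps),

where alpha and beta are independent Matérn (nu = 1) Gaussian fields
represented as SPDE-GMRFs on a shared triangulated mesh.  Each field is
split into a weakly-penalized constant mean (a fixed effect with precision
``fixed_effect_prec``) plus a zero-mean GMRF over mesh vertices, so the
latent vector is

    z = (mu_alpha, mu_beta, alpha_tilde[1..m], beta_tilde[1..m]).

Inference: the latent Gaussian vector is integrated out analytically, giving
a closed-form marginal likelihood for the five hyperparameters
(range_alpha, sd_alpha, range_beta, sd_beta, tau_eps).  An adaptive
random-walk Metropolis sampler explores the hyperparameters on the log
scale under their penalized-complexity and Gamma priors; for each retained
hyperparameter draw one exact joint sample of the latent vector is drawn
from its Gaussian full conditional.  Posterior summaries of ranges,
coefficient surfaces and fitted values are computed from these draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial.distance import pdist, squareform

from .mesh import Mesh
from .priors import PriorConfig
from .spde import SMOOTHNESS_NU

__all__ = [
    "InferenceConfig",
    "SVCPosterior",
    "fit_svc",
    "gmrf_marginal_loglik",
    "posterior_range_summary",
    "predict_coefficients",
    "residual_diagnostics",
    "effective_sample_size",
    "VariogramResult",
]

_HYPER_NAMES = ["range_alpha", "sd_alpha", "range_beta", "sd_beta", "noise_precision"]


@dataclass(frozen=True)
class InferenceConfig:
    """MCMC settings.  ``seed`` is mandatory for reproducibility."""

    seed: int
    n_iter: int = 3000
    n_burn: int = 1000
    thin: int = 5
    n_latent_draws: int = 200
    fixed_effect_prec: float = 1e-6
    adapt_interval: int = 50
    target_accept: float = 0.3
    init_step: float = 0.25


@dataclass
class SVCPosterior:
    """Posterior draws and projectors from :func:`fit_svc`."""

    mesh: Mesh
    routes: pd.DataFrame
    covariate: str
    response: str
    hyper_draws: pd.DataFrame
    latent_draws: np.ndarray  # (n_draws, 2m + 2), empty if n_latent_draws == 0
    projector: sp.csr_matrix
    acceptance_rate: float
    ess: dict
    converged: bool
    flags: list
    config: InferenceConfig

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices

    def _split_latent(self):
        m = self.n_vertices
        ld = self.latent_draws
        return ld[:, 0], ld[:, 1], ld[:, 2 : 2 + m], ld[:, 2 + m :]

    def coefficient_draws(self, a_loc: sp.csr_matrix):
        """Alpha and beta surface draws at locations given their projector."""
        if self.latent_draws.size == 0:
            raise ValueError("fit was run with n_latent_draws=0")
        mu_a, mu_b, fa, fb = self._split_latent()
        alpha = mu_a[:, None] + fa @ a_loc.T.toarray()
        beta = mu_b[:, None] + fb @ a_loc.T.toarray()
        return alpha, beta

    def fitted_draws(self) -> np.ndarray:
        """Draws of the linear predictor at the data locations, (draws, n)."""
        pm = self.routes[self.covariate].to_numpy()
        alpha, beta = self.coefficient_draws(self.projector)
        return alpha + beta * pm[None, :]


class _MarginalLikelihood:
    """Closed-form marginal likelihood of the hyperparameters.

    The latent vector is ``(mu_alpha, mu_beta, alpha_nodes, beta_nodes)``.
    The two weakly-penalized fixed effects would insert dense rows into the
    joint posterior precision and ruin the sparse factorization, so they are
    eliminated by a rank-2 Schur complement: only the 2m-dimensional field
    block is LU-factorized per evaluation.  Field-prior log-determinants come
    from a one-time generalized eigendecomposition of (stiffness, mass),
    using Q_field = tau_s^2 * B C^-1 B with B = kappa^2 C + G, so

        logdet Q_field = 2m log tau_s + logdet C + 2 sum_i log(kappa^2 + w_i)

    with w_i the eigenvalues of C^-1/2 G C^-1/2.  Latent draws use the
    perturb-and-solve identity: x = mu + Q^-1 (tau M' e + s), e ~ N(0, I/tau),
    s ~ N(0, Q_prior), which only needs solves with the factorization.
    """

    def __init__(self, mesh: Mesh, locations, pm, y, fixed_effect_prec=1e-6):
        self.mesh = mesh
        self.m = mesh.n_vertices
        self.p0 = fixed_effect_prec
        c_diag, g = mesh.fem()
        self.c_diag = c_diag
        self.logdet_c = float(np.sum(np.log(c_diag)))
        self._c = sp.diags(c_diag).tocsc()
        self._g = g.tocsc()
        csqi = 1.0 / np.sqrt(c_diag)
        w = csqi[:, None] * g.toarray() * csqi[None, :]
        self.field_eigs = np.clip(np.linalg.eigvalsh(w), 0.0, None)
        self.a = mesh.projector(locations)
        pm = np.asarray(pm, dtype=float)
        y = np.asarray(y, dtype=float)
        self.n = len(y)
        self.pm = pm
        self.y = y
        self.mf = sp.hstack([self.a, sp.diags(pm) @ self.a]).tocsr()
        self.ftf = (self.mf.T @ self.mf).tocsc()
        self.fty = self.mf.T @ y
        self.x = np.column_stack([np.ones(self.n), pm])
        self.xtx = self.x.T @ self.x
        self.xtmf = np.asarray((self.mf.T @ self.x))  # (2m, 2)
        self.xty = self.x.T @ y
        self.yy = float(y @ y)

    def _kappa_tau(self, range_km: float, marginal_sd: float):
        kappa = np.sqrt(8.0 * SMOOTHNESS_NU) / range_km
        tau = 1.0 / (np.sqrt(4.0 * np.pi) * kappa * marginal_sd)
        return kappa, tau

    def field_precision(self, range_km: float, marginal_sd: float) -> sp.csc_matrix:
        kappa, tau = self._kappa_tau(range_km, marginal_sd)
        b = (kappa**2 * self._c + self._g).tocsc()
        q = (tau**2 * (b @ sp.diags(1.0 / self.c_diag) @ b)).tocsc()
        return ((q + q.T) * 0.5).tocsc()  # exact symmetry for the Cholesky

    def field_logdet(self, range_km: float, marginal_sd: float) -> float:
        kappa, tau = self._kappa_tau(range_km, marginal_sd)
        return float(
            2.0 * self.m * np.log(tau)
            + self.logdet_c
            + 2.0 * np.sum(np.log(kappa**2 + self.field_eigs))
        )

    def factorize(self, hp: dict) -> "_PosteriorFactor":
        from scipy.linalg import cholesky_banded

        tau = hp["noise_precision"]
        q_a = self.field_precision(hp["range_alpha"], hp["sd_alpha"])
        q_b = self.field_precision(hp["range_beta"], hp["sd_beta"])
        q_ff = (sp.block_diag([q_a, q_b], format="csc") + tau * self.ftf).tocsr()
        if not hasattr(self, "_perm"):
            from scipy.sparse.csgraph import reverse_cuthill_mckee

            self._perm = np.asarray(reverse_cuthill_mckee(q_ff, symmetric_mode=True))
            qp0 = q_ff[self._perm][:, self._perm].tocoo()
            self._bw = int(np.max(qp0.row - qp0.col))
        qp = q_ff[self._perm][:, self._perm].tocoo()
        k = qp.row - qp.col
        lower = k >= 0
        ab = np.zeros((self._bw + 1, q_ff.shape[0]))
        ab[k[lower], qp.col[lower]] = qp.data[lower]
        chol = cholesky_banded(ab, lower=True, check_finite=False)
        ld_ff = 2.0 * float(np.sum(np.log(chol[0])))
        bmat = tau * self.xtmf  # (2m, 2) cross block
        u = _banded_solve(chol, self._perm, bmat)
        s2 = self.p0 * np.eye(2) + tau * self.xtx - bmat.T @ u
        ld_post = ld_ff + float(np.linalg.slogdet(s2)[1])
        return _PosteriorFactor(chol, self._perm, bmat, u, s2, ld_post)

    def loglik(self, hp: dict, factor: "_PosteriorFactor | None" = None) -> float:
        tau = hp["noise_precision"]
        fac = factor if factor is not None else self.factorize(hp)
        ld_prior = (
            2.0 * np.log(self.p0)
            + self.field_logdet(hp["range_alpha"], hp["sd_alpha"])
            + self.field_logdet(hp["range_beta"], hp["sd_beta"])
        )
        b_x = tau * self.xty
        b_f = tau * self.fty
        mu_x, mu_f = fac.solve(b_x, b_f)
        quad = tau * self.yy - float(b_x @ mu_x + b_f @ mu_f)
        return float(
            0.5 * ld_prior
            - 0.5 * fac.logdet
            + 0.5 * self.n * np.log(tau)
            - 0.5 * self.n * np.log(2.0 * np.pi)
            - 0.5 * quad
        )

    def _field_prior_sample(
        self, range_km: float, marginal_sd: float, rng: np.random.Generator
    ) -> np.ndarray:
        """s ~ N(0, Q_field): s = tau_s (kappa^2 C + G) C^-1/2 u, u ~ N(0, I)."""
        kappa, tau = self._kappa_tau(range_km, marginal_sd)
        u = rng.standard_normal(self.m) / np.sqrt(self.c_diag)
        return tau * (kappa**2 * (self.c_diag * u) + self._g @ u)

    def conditional_latent(self, hp: dict, rng: np.random.Generator) -> np.ndarray:
        """One exact joint draw of the latent vector given hyperparameters."""
        tau = hp["noise_precision"]
        fac = self.factorize(hp)
        mu_x, mu_f = fac.solve(tau * self.xty, tau * self.fty)
        e = rng.standard_normal(self.n) / np.sqrt(tau)
        s_x = np.sqrt(self.p0) * rng.standard_normal(2)
        s_f = np.concatenate(
            [
                self._field_prior_sample(hp["range_alpha"], hp["sd_alpha"], rng),
                self._field_prior_sample(hp["range_beta"], hp["sd_beta"], rng),
            ]
        )
        p_x = tau * (self.x.T @ e) + s_x
        p_f = tau * (self.mf.T @ e) + s_f
        d_x, d_f = fac.solve(p_x, p_f)
        return np.concatenate([mu_x + d_x, mu_f + d_f])


def _banded_solve(chol, perm, rhs):
    """Solve with a banded Cholesky factor under an RCM permutation."""
    from scipy.linalg import cho_solve_banded

    rhs = np.asarray(rhs)
    out = np.empty_like(rhs, dtype=float)
    out[perm] = cho_solve_banded((chol, True), rhs[perm], check_finite=False)
    return out


class _PosteriorFactor:
    """Rank-2 Schur-complement factorization of the joint posterior precision."""

    def __init__(self, chol, perm, bmat, u, s2, logdet):
        self._chol = chol
        self._perm = perm
        self._bmat = bmat
        self._u = u
        self._s2 = s2
        self.logdet = logdet

    def solve(self, b_x: np.ndarray, b_f: np.ndarray):
        """Solve Q_post (x, f) = (b_x, b_f) for the (fixed, field) blocks."""
        w = _banded_solve(self._chol, self._perm, b_f)
        x = np.linalg.solve(self._s2, b_x - self._bmat.T @ w)
        f = w - self._u @ x
        return x, f


def gmrf_marginal_loglik(
    routes: pd.DataFrame,
    mesh: Mesh,
    hyperparameters: dict,
    covariate: str = "pm_std",
    response: str = "richness",
    fixed_effect_prec: float = 1e-6,
) -> float:
    """Marginal log-likelihood of the data at fixed hyperparameters.

    ``hyperparameters`` must supply range_alpha, sd_alpha, range_beta,
    sd_beta and noise_precision.  Exposed so the SPDE-GMRF path can be
    checked against a dense Gaussian-process computation.
    """
    loc = routes[["x_km", "y_km"]].to_numpy()
    ml = _MarginalLikelihood(
        mesh, loc, routes[covariate].to_numpy(), routes[response].to_numpy(),
        fixed_effect_prec,
    )
    return ml.loglik(hyperparameters)


def _log_posterior(ml, priors: PriorConfig, theta: np.ndarray) -> float:
    """Posterior density of the log-scale hyperparameters (with Jacobians)."""
    if np.any(np.abs(theta) > 40):
        return -np.inf
    vals = np.exp(theta)
    hp = dict(zip(_HYPER_NAMES, vals))
    lp = (
        priors.range_alpha.logpdf(hp["range_alpha"])
        + priors.sd_alpha.logpdf(hp["sd_alpha"])
        + priors.range_beta.logpdf(hp["range_beta"])
        + priors.sd_beta.logpdf(hp["sd_beta"])
        + priors.noise.logpdf(hp["noise_precision"])
        + theta.sum()  # Jacobian of the log transform
    )
    if not np.isfinite(lp):
        return -np.inf
    try:
        ll = ml.loglik(hp)
    except np.linalg.LinAlgError:
        # Cholesky failure at numerically extreme proposals: reject the move.
        return -np.inf
    if not np.isfinite(ll):
        return -np.inf
    return lp + ll


def fit_svc(
    routes: pd.DataFrame,
    mesh: Mesh,
    priors: PriorConfig,
    config: InferenceConfig,
    covariate: str = "pm_std",
    response: str = "richness",
) -> SVCPosterior:
    """Fit the SVC model by marginalized adaptive Metropolis sampling.

    Requires at least 30 routes with a standardized covariate; all route
    locations must fall inside the mesh extension.  Non-convergence is
    flagged on the returned posterior, never silent.
    """
    if "retained" in routes:
        routes = routes[routes["retained"]].reset_index(drop=True)
    if len(routes) < 30:
        raise ValueError(f"need at least 30 retained routes, got {len(routes)}")
    pm = routes[covariate].to_numpy(dtype=float)
    if abs(pm.mean()) > 0.01 or abs(pm.std(ddof=1) - 1.0) > 0.05:
        raise ValueError(f"covariate {covariate!r} is not standardized")
    y = routes[response].to_numpy(dtype=float)
    loc = routes[["x_km", "y_km"]].to_numpy()

    ml = _MarginalLikelihood(mesh, loc, pm, y, config.fixed_effect_prec)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # Initialize at prior medians; noise precision from the OLS residual.
    x = np.column_stack([np.ones_like(pm), pm])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resvar = max(np.var(y - x @ coef, ddof=2), 1e-8)
    theta = np.log(
        [
            priors.range_alpha.median,
            priors.sd_alpha.median,
            priors.range_beta.median,
            priors.sd_beta.median,
            1.0 / resvar,
        ]
    )
    lp = _log_posterior(ml, priors, theta)
    if not np.isfinite(lp):
        raise RuntimeError(
            "posterior not finite at the initial hyperparameters "
            f"{dict(zip(_HYPER_NAMES, np.exp(theta)))}"
        )

    d = len(theta)
    step = config.init_step
    prop_chol = np.eye(d)
    history = np.empty((config.n_iter, d))
    kept_theta, kept_lp = [], []
    n_accept = 0
    accept_window = 0

    for it in range(config.n_iter):
        prop = theta + step * (prop_chol @ rng.standard_normal(d))
        lp_prop = _log_posterior(ml, priors, prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            n_accept += 1
            accept_window += 1
        history[it] = theta
        in_burn = it < config.n_burn
        if in_burn and (it + 1) % config.adapt_interval == 0:
            rate = accept_window / config.adapt_interval
            step *= np.exp(0.7 * (rate - config.target_accept))
            accept_window = 0
            if it + 1 >= config.n_burn // 2:
                cov = np.cov(history[it // 2 : it + 1].T)
                cov += 1e-8 * np.eye(d)
                try:
                    prop_chol = np.linalg.cholesky(cov / np.mean(np.diag(cov)))
                except np.linalg.LinAlgError:
                    pass
        if not in_burn and (it - config.n_burn) % config.thin == 0:
            kept_theta.append(theta.copy())
            kept_lp.append(lp)

    kept = np.exp(np.array(kept_theta))
    hyper_draws = pd.DataFrame(kept, columns=_HYPER_NAMES)
    hyper_draws["log_posterior"] = kept_lp

    n_latent = min(config.n_latent_draws, len(kept))
    if n_latent > 0:
        pick = np.linspace(0, len(kept) - 1, n_latent).round().astype(int)
        latent = np.empty((n_latent, 2 * mesh.n_vertices + 2))
        for k, idx in enumerate(pick):
            hp = dict(zip(_HYPER_NAMES, kept[idx]))
            latent[k] = ml.conditional_latent(hp, rng)
    else:
        latent = np.empty((0, 2 * mesh.n_vertices + 2))

    acc_rate = n_accept / config.n_iter
    ess = {
        name: effective_sample_size(np.log(hyper_draws[name].to_numpy()))
        for name in _HYPER_NAMES
    }
    flags = []
    if not 0.05 <= acc_rate <= 0.7:
        flags.append(f"acceptance rate {acc_rate:.2f} outside [0.05, 0.7]")
    low = [k for k, v in ess.items() if v < 20]
    if low:
        flags.append(f"low effective sample size for {low}")
    return SVCPosterior(
        mesh=mesh,
        routes=routes,
        covariate=covariate,
        response=response,
        hyper_draws=hyper_draws,
        latent_draws=latent,
        projector=ml.a,
        acceptance_rate=acc_rate,
        ess=ess,
        converged=not flags,
        flags=flags,
        config=config,
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence of autocovariances."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    # Sum consecutive pairs while they stay positive.
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def posterior_range_summary(fit: SVCPosterior, field: str = "beta"):
    """(median, q2.5, q97.5) of a field's spatial-range posterior, in km."""
    if field not in ("alpha", "beta"):
        raise ValueError("field must be 'alpha' or 'beta'")
    draws = fit.hyper_draws[f"range_{field}"].to_numpy()
    q025, med, q975 = np.quantile(draws, [0.025, 0.5, 0.975])
    return float(med), float(q025), float(q975)


def predict_coefficients(fit: SVCPosterior, locations) -> pd.DataFrame:
    """Posterior (median, q2.5, q97.5) of alpha and beta at locations."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    a_loc = fit.mesh.projector(locations)
    alpha, beta = fit.coefficient_draws(a_loc)
    qs = [0.5, 0.025, 0.975]
    aq = np.quantile(alpha, qs, axis=0)
    bq = np.quantile(beta, qs, axis=0)
    return pd.DataFrame(
        {
            "x_km": locations[:, 0],
            "y_km": locations[:, 1],
            "alpha_median": aq[0],
            "alpha_q025": aq[1],
            "alpha_q975": aq[2],
            "beta_median": bq[0],
            "beta_q025": bq[1],
            "beta_q975": bq[2],
        }
    )


@dataclass
class VariogramResult:
    bin_centers: np.ndarray
    semivariance: np.ndarray
    counts: np.ndarray
    envelope_low: np.ndarray | None = None
    envelope_high: np.ndarray | None = None


def empirical_variogram(
    locations: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
    max_lag: float | None = None,
    n_permutations: int = 0,
    rng: np.random.Generator | int | None = None,
) -> VariogramResult:
    """Binned empirical semivariogram with an optional permutation envelope.

    The envelope is the pointwise 2.5-97.5% band of semivariograms computed
    after randomly permuting values across locations, i.e. the no-spatial-
    structure reference.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(locations)
    if max_lag is None:
        max_lag = 0.5 * d.max()
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges) - 1
    in_range = (which >= 0) & (which < n_bins)
    idx = which[in_range]
    counts = np.bincount(idx, minlength=n_bins)

    def gamma_of(v):
        sq = 0.5 * pdist(v[:, None], metric="sqeuclidean")[in_range]
        sums = np.bincount(idx, weights=sq, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / counts, np.nan)

    gamma = gamma_of(values)
    env_lo = env_hi = None
    if n_permutations > 0:
        rng = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )
        sims = np.array(
            [gamma_of(rng.permutation(values)) for _ in range(n_permutations)]
        )
        env_lo = np.nanquantile(sims, 0.025, axis=0)
        env_hi = np.nanquantile(sims, 0.975, axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VariogramResult(centers, gamma, counts, env_lo, env_hi)


def residual_diagnostics(
    fit: SVCPosterior,
    n_bins: int = 12,
    n_permutations: int = 99,
):
    """Residuals vs fitted values plus a variogram with permutation envelope.

    Residuals are the data minus the posterior-median fitted values.
    """
    y = fit.routes[fit.response].to_numpy(dtype=float)
    fitted = np.median(fit.fitted_draws(), axis=0)
    residuals = y - fitted
    loc = fit.routes[["x_km", "y_km"]].to_numpy()
    vario = empirical_variogram(
        loc,
        residuals,
        n_bins=n_bins,
        n_permutations=n_permutations,
        rng=np.random.default_rng(np.random.SeedSequence([fit.config.seed, 17])),
    )
    return residuals, fitted, vario
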