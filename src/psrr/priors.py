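"""Penalized-complexity priors for the Matérn hyperparameters.

PC priors are calibrated by a single tail statement.  For the spatial range
of a two-dimensional Matérn field the prior has CDF

    P(rho <= r) = exp(-lam / r),        lam = -rho0 * ln(1 - p_exceed),

so that P(rho > rho0) = p_exceed; with p_exceed = 0.5 the prior median is
exactly rho0.  The marginal standard deviation gets an exponential prior

    P(sigma > s) = exp(-lam2 * s),      lam2 = -ln(p_exceed) / sigma0,

so that P(sigma > sigma0) = p_exceed.  The observation-noise precision gets
a Gamma prior, Gamma(shape=1, rate=1e-5) by default (a log-gamma prior on
the log precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PCPriorRange", "PCPriorSD", "NoisePrecisionPrior", "PriorConfig"]


@dataclass(frozen=True)
class PCPriorRange:
    """PC prior on the spatial range (km) of a 2-D Matérn field."""

    rho0: float
    p_exceed: float = 0.5

    def __post_init__(self):
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if not 0 < self.p_exceed < 1:
            raise ValueError("p_exceed must be in (0, 1)")

    @property
    def lam(self) -> float:
        return -self.rho0 * np.log1p(-self.p_exceed)

    def logpdf(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                rho > 0,
                np.log(self.lam) - 2.0 * np.log(rho) - self.lam / rho,
                -np.inf,
            )
        return out if out.ndim else float(out)

    def cdf(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        out = np.where(rho > 0, np.exp(-self.lam / np.maximum(rho, 1e-300)), 0.0)
        return out if out.ndim else float(out)

    def quantile(self, p: float) -> float:
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        return -self.lam / np.log(p)

    @property
    def median(self) -> float:
        return self.quantile(0.5)


@dataclass(frozen=True)
class PCPriorSD:
    """Exponential PC prior on a field's marginal standard deviation."""

    sigma0: float
    p_exceed: float = 0.5

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 0 < self.p_exceed < 1:
            raise ValueError("p_exceed must be in (0, 1)")

    @property
    def lam(self) -> float:
        return -np.log(self.p_exceed) / self.sigma0

    def logpdf(self, sigma) -> np.ndarray:
        sigma = np.asarray(sigma, dtype=float)
        out = np.where(sigma >= 0, np.log(self.lam) - self.lam * sigma, -np.inf)
        return out if out.ndim else float(out)

    def cdf(self, sigma) -> np.ndarray:
        sigma = np.asarray(sigma, dtype=float)
        out = np.where(sigma > 0, -np.expm1(-self.lam * sigma), 0.0)
        return out if out.ndim else float(out)

    def quantile(self, p: float) -> float:
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        return -np.log1p(-p) / self.lam

    @property
    def median(self) -> float:
        return self.quantile(0.5)


@dataclass(frozen=True)
class NoisePrecisionPrior:
    """Gamma prior on the Gaussian observation-noise precision."""

    shape: float = 1.0
    rate: float = 1e-5

    def logpdf(self, tau) -> float:
        return stats.gamma.logpdf(tau, a=self.shape, scale=1.0 / self.rate)


@dataclass(frozen=True)
class PriorConfig:
    """Priors for both spatial fields plus the noise precision.

    Defaults reproduce the analysis settings: range prior median 2,243 km
    (half the maximum inter-route distance in the original study), marginal
    SD prior median 1, and Gamma(1, 1e-5) on the noise precision.
    """

    range_alpha: PCPriorRange = PCPriorRange(2243.0, 0.5)
    sd_alpha: PCPriorSD = PCPriorSD(1.0, 0.5)
    range_beta: PCPriorRange = PCPriorRange(2243.0, 0.5)
    sd_beta: PCPriorSD = PCPriorSD(1.0, 0.5)
    noise: NoisePrecisionPrior = NoisePrecisionPrior()

    @classmethod
    def with_range_threshold(cls, rho0: float, sd0: float = 1.0) -> "PriorConfig":
        return cls(
            range_alpha=PCPriorRange(rho0, 0.5),
            sd_alpha=PCPriorSD(sd0, 0.5),
            range_beta=PCPriorRange(rho0, 0.5),
            sd_beta=PCPriorSD(sd0, 0.5),
        )
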