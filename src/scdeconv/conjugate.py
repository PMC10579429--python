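"""Normal-inverse-Wishart conjugacy and incremental sufficient statistics.

A multivariate-normal basis with unknown mean and covariance admits the
conjugate prior

    mu | Sigma ~ N(mu0, Sigma / kappa0),      Sigma ~ InvWishart(Sigma0, nu0).

Given n assigned cells with mean x_bar and (1/n-normalized) scatter S2, the
conditional, marginal and predictive distributions all have closed forms; the
Gibbs samplers in this package only ever touch data through (n, x_bar, S2),
which can be updated in O(d^2) when one cell is added or removed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import invwishart

from ._utils import LOG_2PI, as_rng, chol_with_jitter
from .events import EventTable

__all__ = [
    "NIWHyperparams",
    "ComponentStats",
    "update_stats_add",
    "update_stats_remove",
    "niw_sample_mean",
    "niw_sample_covariance_conditional",
    "niw_sample_covariance_marginal",
    "posterior_predictive_logpdf",
    "default_hyperparams",
]


@dataclass(frozen=True)
class NIWHyperparams:
    """Prior mean mu0, confidence kappa0, prior scale Sigma0, confidence nu0,
    plus the Dirichlet / Dirichlet-process concentration alpha."""

    mu0: np.ndarray
    kappa0: float
    sigma0: np.ndarray
    nu0: float
    alpha: float = 1.0

    def __post_init__(self):
        mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        sigma0 = np.atleast_2d(np.asarray(self.sigma0, dtype=float))
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "sigma0", sigma0)
        d = mu0.shape[0]
        if sigma0.shape != (d, d):
            raise ValueError("sigma0 shape incompatible with mu0")
        if not self.kappa0 > 0:
            raise ValueError("kappa0 must be positive")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.nu0 > d - 1:
            raise ValueError(f"nu0 must exceed d-1={d - 1} for a proper prior")
        np.linalg.cholesky(sigma0)

    @property
    def dimension(self) -> int:
        return self.mu0.shape[0]


@dataclass(frozen=True)
class ComponentStats:
    """Count n, mean vector and 1/n-normalized scatter matrix of the cells
    currently assigned to one component.  Empty stats are all zeros."""

    n: int
    mean: np.ndarray
    scatter: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        scatter = np.atleast_2d(np.asarray(self.scatter, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "scatter", scatter)
        if self.n < 0:
            raise ValueError("n must be >= 0")

    @classmethod
    def empty(cls, d: int) -> "ComponentStats":
        return cls(0, np.zeros(d), np.zeros((d, d)))

    @classmethod
    def from_data(cls, x: np.ndarray) -> "ComponentStats":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        mean = x.mean(axis=0)
        diff = x - mean
        return cls(n, mean, diff.T @ diff / n)

    @property
    def dimension(self) -> int:
        return self.mean.shape[0]


def update_stats_add(stats: ComponentStats, x) -> ComponentStats:
    """Add one cell: exact O(d^2) update of (n, mean, scatter)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n_new = stats.n + 1
    mean_new = (stats.n * stats.mean + x) / n_new
    second = (
        stats.n * stats.scatter
        + stats.n * np.outer(stats.mean, stats.mean)
        + np.outer(x, x)
    ) / n_new
    scatter = second - np.outer(mean_new, mean_new)
    scatter = 0.5 * (scatter + scatter.T)
    return ComponentStats(n_new, mean_new, scatter)


def update_stats_remove(stats: ComponentStats, x) -> ComponentStats:
    """Remove one cell; removing the last one yields the empty stats."""
    if stats.n < 1:
        raise ValueError("cannot remove a cell from empty statistics")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if stats.n == 1:
        return ComponentStats.empty(stats.dimension)
    n_new = stats.n - 1
    mean_new = (stats.n * stats.mean - x) / n_new
    second = (
        stats.n * stats.scatter
        + stats.n * np.outer(stats.mean, stats.mean)
        - np.outer(x, x)
    ) / n_new
    scatter = second - np.outer(mean_new, mean_new)
    scatter = 0.5 * (scatter + scatter.T)
    return ComponentStats(n_new, mean_new, scatter)


# --------------------------------------------------------------------------
# conditional / marginal draws
# --------------------------------------------------------------------------

def _draw_mvn(rng, mean, cov):
    L = chol_with_jitter(cov)
    return mean + L @ rng.standard_normal(mean.shape[0])


def niw_sample_mean(stats: ComponentStats, covariance, prior: NIWHyperparams, seed=None):
    """Draw mu ~ N(mu_tilde, Sigma/(n+kappa0)) with
    mu_tilde = (n x_bar + kappa0 mu0)/(n + kappa0), conditional on Sigma."""
    rng = as_rng(seed)
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    denom = stats.n + prior.kappa0
    mu_tilde = (stats.n * stats.mean + prior.kappa0 * prior.mu0) / denom
    return _draw_mvn(rng, mu_tilde, covariance / denom)


def _cond_scale(stats: ComponentStats, mean, prior: NIWHyperparams) -> np.ndarray:
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    d1 = stats.mean - mean
    d2 = mean - prior.mu0
    return (
        stats.n * stats.scatter
        + stats.n * np.outer(d1, d1)
        + prior.kappa0 * np.outer(d2, d2)
        + prior.sigma0
    )


def niw_sample_covariance_conditional(
    stats: ComponentStats, mean, prior: NIWHyperparams, seed=None
) -> np.ndarray:
    """Sigma ~ InvWishart(scale, n + nu0 + 1) conditional on the mean, with
    scale = n S2 + n (x_bar-mu)(x_bar-mu)' + kappa0 (mu-mu0)(mu-mu0)' + Sigma0."""
    rng = as_rng(seed)
    scale = _cond_scale(stats, mean, prior)
    scale = 0.5 * (scale + scale.T)
    np.linalg.cholesky(scale)  # invariant: must be SPD for valid inputs
    df = stats.n + prior.nu0 + 1
    return np.atleast_2d(invwishart.rvs(df=df, scale=scale, random_state=rng))


def _marginal_scale(stats: ComponentStats, prior: NIWHyperparams) -> np.ndarray:
    diff = stats.mean - prior.mu0
    shrink = prior.kappa0 * stats.n / (prior.kappa0 + stats.n)
    return stats.n * stats.scatter + shrink * np.outer(diff, diff) + prior.sigma0


def niw_sample_covariance_marginal(
    stats: ComponentStats, prior: NIWHyperparams, seed=None
) -> np.ndarray:
    """Sigma ~ InvWishart(scale, n + nu0 + 1) with the mean integrated out:
    scale = n S2 + (kappa0 n/(kappa0+n)) (x_bar-mu0)(x_bar-mu0)' + Sigma0."""
    rng = as_rng(seed)
    scale = _marginal_scale(stats, prior)
    scale = 0.5 * (scale + scale.T)
    df = stats.n + prior.nu0 + 1
    return np.atleast_2d(invwishart.rvs(df=df, scale=scale, random_state=rng))


# --------------------------------------------------------------------------
# posterior predictive (collapsed) density
# --------------------------------------------------------------------------

def predictive_t_params(stats: ComponentStats, prior: NIWHyperparams):
    """(df, location, scale matrix) of the multivariate-t posterior predictive.

    df = n + nu0 + 1 - p; location = (n x_bar + kappa0 mu0)/(n + kappa0);
    scale = Sigma_y / df with Sigma_y = (m1 (mu0-x_bar)(mu0-x_bar)' + n S2 +
    Sigma0) / m0, m0 = (n+kappa0)/(n+kappa0+1),
    m1 = (n kappa0/(n+kappa0) + n kappa0)/(n+kappa0+1).
    """
    n, k0, p = stats.n, prior.kappa0, prior.dimension
    df = n + prior.nu0 + 1 - p
    if df <= 0:
        raise ValueError(
            f"predictive degrees of freedom n+nu0+1-p = {df} <= 0 "
            f"(n={n}, nu0={prior.nu0}, p={p})"
        )
    m0 = (n + k0) / (n + k0 + 1.0)
    m1 = (n * k0 / (n + k0) + n * k0) / (n + k0 + 1.0)
    loc = (n * stats.mean + k0 * prior.mu0) / (n + k0)
    diff = prior.mu0 - stats.mean
    sigma_y = (m1 * np.outer(diff, diff) + n * stats.scatter + prior.sigma0) / m0
    return df, loc, sigma_y / df


def _mvt_logpdf(x: np.ndarray, df: float, loc: np.ndarray, shape: np.ndarray):
    """Multivariate Student-t log density; x of shape (n, d)."""
    p = loc.shape[0]
    L = chol_with_jitter(shape)
    sol = solve_triangular(L, (x - loc).T, lower=True)
    quad = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return (
        math.lgamma(0.5 * (df + p))
        - math.lgamma(0.5 * df)
        - 0.5 * p * math.log(df * math.pi)
        - 0.5 * logdet
        - 0.5 * (df + p) * np.log1p(quad / df)
    )


def posterior_predictive_logpdf(y, stats: ComponentStats, prior: NIWHyperparams):
    """Log density of a new point under the collapsed NIW posterior.

    This is the multivariate-t used by the Dirichlet-process reassignment
    weights; with n=0 it is the prior predictive.
    """
    df, loc, shape = predictive_t_params(stats, prior)
    p = prior.dimension
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0 or (y.ndim == 1 and p > 1)
    pts = y.reshape(-1, p)
    out = _mvt_logpdf(pts, df, loc, shape)
    return float(out[0]) if scalar else out


def default_hyperparams(
    data: EventTable, alpha: float = 1.0, kappa0: float = 1.0, nu0: float = None
) -> NIWHyperparams:
    """Weakly-informative prior centered on the dataset moments.

    mu0 and Sigma0 are the dataset mean and covariance, which places the prior
    mass where the density lies; kappa0=1 and nu0=d+2 (the smallest value with
    a finite prior mean of Sigma) are defaults the large-sample posterior is
    insensitive to.  For fat-tailed data the moment-based Sigma0 can be very
    wide; callers may override it with a narrower scale.
    """
    if data.n_events < 2:
        raise ValueError("need at least two events to set data-driven hyperparameters")
    x = data.values
    mu0 = x.mean(axis=0)
    diff = x - mu0
    sigma0 = diff.T @ diff / x.shape[0]
    variances = np.diag(sigma0)
    if np.any(variances <= 0):
        bad = [data.channel_names[i] for i in np.where(variances <= 0)[0]]
        raise ValueError(
            f"channels {bad} have zero variance; rescale or drop them before fitting"
        )
    d = data.dimension
    if nu0 is None:
        nu0 = d + 2
    return NIWHyperparams(mu0=mu0, kappa0=kappa0, sigma0=sigma0, nu0=nu0, alpha=alpha)
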