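"""Dirichlet-process Gaussian mixture Gibbs sampler.

Instead of fixing the number of components, cells are reseated one at a time
by the Chinese-restaurant rule: an occupied component attracts a cell with
weight n_k/(n+alpha-1) times its collapsed posterior-predictive density (a
multivariate Student-t computed from the component's sufficient statistics
with the cell removed), and a new component is opened with weight
alpha/(n+alpha-1) times the prior predictive.  Components left empty are
deleted on the spot.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._utils import as_rng
from .conjugate import (
    ComponentStats,
    NIWHyperparams,
    default_hyperparams,
    niw_sample_covariance_marginal,
    niw_sample_mean,
    posterior_predictive_logpdf,
)
from .events import EventTable
from .finite import ChainConfig, group_stats
from .mixture import MixtureModel

__all__ = [
    "InfiniteSamplerState",
    "crp_reassignment_probs",
    "crp_log_weights",
    "reassign_sweep",
    "run_infinite_chain",
]


@dataclass
class InfiniteSamplerState:
    """Dynamic active set: per-cell labels, per-component statistics, and the
    last drawn parameters (weights/means/covariances, one row per active
    component)."""

    assignments: np.ndarray
    stats: list[ComponentStats]
    weights: np.ndarray = None
    means: np.ndarray = None
    covariances: np.ndarray = None
    iteration: int = 0

    @property
    def n_active(self) -> int:
        return len(self.stats)

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.n for s in self.stats])

    def mixture(self, channel_names=None) -> MixtureModel:
        w = self.weights / self.weights.sum()
        return MixtureModel.from_arrays(w, self.means, self.covariances, channel_names)


def _prior_normal_logpdf(x: np.ndarray, prior: NIWHyperparams) -> float:
    """log N(x | mu0, Sigma0 (kappa0+1)/kappa0): the 'normal' flavor of the
    new-component predictive (moment-matched location/scale, lighter tails
    than the prior-predictive t)."""
    d = prior.dimension
    cov = prior.sigma0 * (prior.kappa0 + 1.0) / prior.kappa0
    diff = x - prior.mu0
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff)
    return float(
        -0.5 * d * math.log(2 * math.pi)
        - np.sum(np.log(np.diag(chol)))
        - 0.5 * np.dot(sol, sol)
    )


def _predictive_1d(x: float, st: ComponentStats, prior: NIWHyperparams) -> float:
    """Fast scalar path of the collapsed predictive log density (d=1)."""
    n, k0 = st.n, prior.kappa0
    nu0 = prior.nu0
    mu0 = prior.mu0[0]
    s0 = prior.sigma0[0, 0]
    df = n + nu0  # n + nu0 + 1 - p with p = 1
    nk = n + k0
    m0 = nk / (nk + 1.0)
    m1 = (n * k0 / nk + n * k0) / (nk + 1.0)
    xbar = st.mean[0]
    loc = (n * xbar + k0 * mu0) / nk
    sigma_y = (m1 * (mu0 - xbar) ** 2 + n * st.scatter[0, 0] + s0) / m0
    shape = sigma_y / df
    z2 = (x - loc) ** 2 / shape
    return (
        math.lgamma(0.5 * (df + 1))
        - math.lgamma(0.5 * df)
        - 0.5 * math.log(df * math.pi * shape)
        - 0.5 * (df + 1) * math.log1p(z2 / df)
    )


def crp_log_weights(
    x: np.ndarray,
    stats: list[ComponentStats],
    n_total: int,
    prior: NIWHyperparams,
    new_predictive: str = "t",
) -> np.ndarray:
    """Unnormalized log seating weights for one cell (x already removed).

    Occupied component k: log[n_k/(n+alpha-1)] + predictive log density; new
    component: log[alpha/(n+alpha-1)] + prior-predictive log density.  The
    ``new_predictive`` flag selects the prior-predictive t ("t", default), a
    normal with the prior's moment-matched parameters ("normal"), or a
    constant ("uniform", for exchangeability diagnostics where the seating
    must depend on the counts alone).
    """
    d = prior.dimension
    denom = math.log(n_total + prior.alpha - 1.0)
    out = np.empty(len(stats) + 1)
    x1 = float(x[0]) if d == 1 else np.asarray(x, dtype=float)
    for k, st in enumerate(stats):
        if new_predictive == "uniform":
            pred = 0.0
        elif d == 1:
            pred = _predictive_1d(x1, st, prior)
        else:
            pred = posterior_predictive_logpdf(x1, st, prior)
        out[k] = math.log(st.n) - denom + pred
    if new_predictive == "uniform":
        pred_new = 0.0
    elif new_predictive == "normal":
        pred_new = _prior_normal_logpdf(np.atleast_1d(x), prior)
    elif d == 1:
        pred_new = _predictive_1d(x1, ComponentStats.empty(1), prior)
    else:
        pred_new = posterior_predictive_logpdf(x1, ComponentStats.empty(d), prior)
    out[-1] = math.log(prior.alpha) - denom + pred_new
    return out


def crp_reassignment_probs(
    x,
    state: InfiniteSamplerState,
    prior: NIWHyperparams,
    new_predictive: str = "t",
) -> np.ndarray:
    """Normalized seating probabilities over (active components, new)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    logw = crp_log_weights(
        x, state.stats, len(state.assignments), prior, new_predictive
    )
    logw = logw - logw.max()
    p = np.exp(logw)
    return p / p.sum()


def _seat(probs_log: np.ndarray, rng: np.random.Generator) -> int:
    m = probs_log.max()
    p = np.exp(probs_log - m)
    cum = np.cumsum(p)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def reassign_sweep(
    data: EventTable,
    state: InfiniteSamplerState,
    prior: NIWHyperparams,
    seed=None,
    order: np.ndarray = None,
    new_predictive: str = "t",
) -> InfiniteSamplerState:
    """One full reseating pass: remove each cell (deleting a component it
    leaves empty), compute CRP weights, seat it, update statistics
    incrementally; a newly opened component starts with n=1, mean=x, S2=0."""
    rng = as_rng(seed)
    x = data.values
    n_total = data.n_events
    labels = state.assignments.copy()
    stats = list(state.stats)
    if order is None:
        order = range(n_total)
    d = data.dimension
    zero = np.zeros((d, d))
    for i in order:
        xi = x[i]
        j = labels[i]
        if stats[j].n == 1:
            # singleton: drop the component and relabel the survivors
            del stats[j]
            labels[labels > j] -= 1
        else:
            stats[j] = _remove_fast(stats[j], xi)
        logw = crp_log_weights(xi, stats, n_total, prior, new_predictive)
        k = _seat(logw, rng)
        if k == len(stats):
            stats.append(ComponentStats(1, xi.copy(), zero))
        else:
            stats[k] = _add_fast(stats[k], xi)
        labels[i] = k
    return replace(state, assignments=labels, stats=stats)


def _add_fast(st: ComponentStats, x: np.ndarray) -> ComponentStats:
    n_new = st.n + 1
    mean_new = (st.n * st.mean + x) / n_new
    second = (
        st.n * st.scatter + st.n * np.outer(st.mean, st.mean) + np.outer(x, x)
    ) / n_new
    return ComponentStats(n_new, mean_new, second - np.outer(mean_new, mean_new))


def _remove_fast(st: ComponentStats, x: np.ndarray) -> ComponentStats:
    n_new = st.n - 1
    mean_new = (st.n * st.mean - x) / n_new
    second = (
        st.n * st.scatter + st.n * np.outer(st.mean, st.mean) - np.outer(x, x)
    ) / n_new
    scatter = second - np.outer(mean_new, mean_new)
    # exact scatters are PSD; clamp the tiny negative diagonal drift that
    # floating-point cancellation can leave behind
    np.fill_diagonal(scatter, np.maximum(np.diag(scatter), 0.0))
    return ComponentStats(n_new, mean_new, scatter)


def _sample_active_params(
    data: EventTable,
    labels: np.ndarray,
    k: int,
    prior: NIWHyperparams,
    rng: np.random.Generator,
):
    """Weights ~ Dirichlet(n_j + alpha); per component the covariance from the
    marginal inverse-Wishart form, then the mean given that covariance."""
    ns, means_hat, scatters = group_stats(data.values, labels, k)
    weights = rng.dirichlet(ns + prior.alpha)
    d = data.dimension
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    for j in range(k):
        st = ComponentStats(int(ns[j]), means_hat[j], scatters[j])
        covs[j] = niw_sample_covariance_marginal(st, prior, rng)
        means[j] = niw_sample_mean(st, covs[j], prior, rng)
    return weights, means, covs


def run_infinite_chain(
    data: EventTable,
    config: ChainConfig,
    prior: NIWHyperparams = None,
    new_predictive: str = "t",
    shuffle_order: bool = False,
) -> list[MixtureModel]:
    """Run the Dirichlet-process chain.  Returns thinned post-burn-in draws,
    each a MixtureModel over that sweep's active components.

    The chain starts from a single cluster holding all cells: one-site
    reseating opens new components easily (singleton creation) but merges
    co-located components only through rare low-probability moves, so a
    partitioned initialization (e.g. k-means slices of a unimodal cloud) can
    persist for many sweeps; config.n_components is therefore ignored here.
    """
    if prior is None:
        prior = default_hyperparams(data)
    rng = as_rng(config.seed)
    labels = np.zeros(data.n_events, dtype=int)
    stats = [ComponentStats.from_data(data.values)]
    state = InfiniteSamplerState(assignments=labels, stats=stats)
    draws: list[MixtureModel] = []
    n_total = data.n_events
    for it in range(config.n_iterations):
        order = rng.permutation(n_total) if shuffle_order else None
        state = reassign_sweep(
            data, state, prior, rng, order=order, new_predictive=new_predictive
        )
        w, mu, cov = _sample_active_params(
            data, state.assignments, state.n_active, prior, rng
        )
        state = replace(
            state, weights=w, means=mu, covariances=cov, iteration=it + 1
        )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            draws.append(state.mixture(data.channel_names))
    return draws
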