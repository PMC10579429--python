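"""Gibbs sampler for a finite Bayesian Gaussian mixture.

This is the sampler used to fit the autofluorescence (noise) data, and also
the "null model" that fits convolved data directly while ignoring the noise.
Each sweep alternates three conditional draws: per-cell indicator variables,
Dirichlet weights with symmetric concentration alpha/K, and per-component
covariance-then-mean draws from the normal-inverse-Wishart conditionals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from ._utils import LOG_2PI, as_rng, chol_with_jitter
from .conjugate import (
    ComponentStats,
    NIWHyperparams,
    default_hyperparams,
    niw_sample_covariance_conditional,
    niw_sample_mean,
)
from .events import EventTable
from .mixture import MixtureModel

__all__ = [
    "ChainConfig",
    "FiniteSamplerState",
    "sample_indicators",
    "sample_weights",
    "sample_component_params",
    "run_finite_chain",
]


@dataclass
class ChainConfig:
    """MCMC settings: number of components K, sweep count, burn-in, thinning,
    seed and the initialization method ("kmeans" or "random")."""

    n_components: int = 4
    n_iterations: int = 2000
    burn_in: int = 1000
    thin: int = 10
    seed: int = 0
    init_method: str = "kmeans"

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init_method not in ("kmeans", "random"):
            raise ValueError("init_method must be 'kmeans' or 'random'")


@dataclass
class FiniteSamplerState:
    """Assignments, per-component statistics and current mixture parameters."""

    assignments: np.ndarray          # (N,) ints in [0, K)
    weights: np.ndarray              # (K,)
    means: np.ndarray                # (K, d)
    covariances: np.ndarray          # (K, d, d)
    iteration: int = 0

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_components)

    def stats(self, data: EventTable) -> list[ComponentStats]:
        ns, means, scatters = group_stats(
            data.values, self.assignments, self.n_components
        )
        return [
            ComponentStats(int(n), m, s) for n, m, s in zip(ns, means, scatters)
        ]

    def mixture(self, channel_names=None) -> MixtureModel:
        w = self.weights / self.weights.sum()
        return MixtureModel.from_arrays(w, self.means, self.covariances, channel_names)


def group_stats(x: np.ndarray, labels: np.ndarray, k: int):
    """Batch per-component count, mean and 1/n scatter (vectorized)."""
    n, d = x.shape
    ns = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, d))
    seconds = np.zeros((k, d, d))
    for a in range(d):
        sums[:, a] = np.bincount(labels, weights=x[:, a], minlength=k)
        for b in range(a, d):
            m = np.bincount(labels, weights=x[:, a] * x[:, b], minlength=k)
            seconds[:, a, b] = m
            seconds[:, b, a] = m
    safe = np.maximum(ns, 1.0)
    means = sums / safe[:, None]
    scatters = seconds / safe[:, None, None] - np.einsum(
        "ka,kb->kab", means, means
    )
    scatters[ns == 0] = 0.0
    means[ns == 0] = 0.0
    return ns, means, scatters


def component_log_likelihoods(x: np.ndarray, means, covariances) -> np.ndarray:
    """(N, K) matrix of log N(x_i | mu_k, Sigma_k)."""
    n, d = x.shape
    k = means.shape[0]
    out = np.empty((n, k))
    for j in range(k):
        L = chol_with_jitter(covariances[j])
        sol = solve_triangular(L, (x - means[j]).T, lower=True)
        quad = np.sum(sol * sol, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, j] = -0.5 * (d * LOG_2PI + logdet + quad)
    return out


def categorical_rows(log_weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one index per row from unnormalized log-weights.

    Rows whose weights all underflow fall back to the max-log-weight index
    with a warning.
    """
    norm = logsumexp(log_weights, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    probs = np.exp(log_weights - np.where(np.isfinite(norm), norm, 0.0))
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} cells had all component weights underflow; "
            "assigned by max log-weight",
            RuntimeWarning,
        )
        probs[bad] = 0.0
        probs[bad, np.argmax(log_weights[bad], axis=1)] = 1.0
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    u = rng.random((log_weights.shape[0], 1))
    return (u > cum).sum(axis=1)


def sample_indicators(
    data: EventTable, state: FiniteSamplerState, seed=None
) -> FiniteSamplerState:
    """Per-cell multinomial draw with weights w_jk proportional to
    omega_j N(x_i | mu_j, Sigma_j)."""
    rng = as_rng(seed)
    logw = component_log_likelihoods(
        data.values, state.means, state.covariances
    ) + np.log(np.maximum(state.weights, 1e-300))
    labels = categorical_rows(logw, rng)
    return replace(state, assignments=labels)


def sample_weights(
    state: FiniteSamplerState, prior: NIWHyperparams, seed=None
) -> FiniteSamplerState:
    """weights ~ Dirichlet(n_j + alpha/K) (symmetric concentration)."""
    rng = as_rng(seed)
    conc = state.counts + prior.alpha / state.n_components
    w = rng.dirichlet(conc)
    return replace(state, weights=w)


def sample_component_params(
    data: EventTable, state: FiniteSamplerState, prior: NIWHyperparams, seed=None
) -> FiniteSamplerState:
    """Per component: covariance from its inverse-Wishart conditional (given
    the current mean), then the mean given the new covariance.  Components
    with no assigned cells draw from the prior-only conditionals."""
    rng = as_rng(seed)
    stats = state.stats(data)
    means = state.means.copy()
    covs = state.covariances.copy()
    for j, st in enumerate(stats):
        covs[j] = niw_sample_covariance_conditional(st, means[j], prior, rng)
        means[j] = niw_sample_mean(st, covs[j], prior, rng)
    return replace(state, means=means, covariances=covs)


def _initial_state(
    data: EventTable, config: ChainConfig, rng: np.random.Generator
) -> FiniteSamplerState:
    x = data.values
    n, d = x.shape
    k = config.n_components
    if config.init_method == "kmeans" and k > 1:
        km = KMeans(
            n_clusters=k,
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(x)
    else:
        labels = rng.integers(k, size=n)
    ns, means, scatters = group_stats(x, labels, k)
    # empirical initialization: mu_j = x_bar_j, Sigma_j = S2_j, w_j = n_j / n;
    # degenerate groups (empty or singular scatter) fall back to the dataset
    # moments so the first sweep starts from a valid mixture
    overall = ComponentStats.from_data(x)
    for j in range(k):
        singular = ns[j] < 2 or np.any(np.diag(scatters[j]) <= 0)
        if not singular:
            try:
                np.linalg.cholesky(scatters[j])
            except np.linalg.LinAlgError:
                singular = True
        if singular:
            if ns[j] == 0:
                means[j] = overall.mean
            scatters[j] = overall.scatter
    weights = np.maximum(ns, 1.0)
    weights = weights / weights.sum()
    return FiniteSamplerState(
        assignments=labels,
        weights=weights,
        means=means,
        covariances=scatters,
        iteration=0,
    )


def run_finite_chain(
    data: EventTable,
    config: ChainConfig,
    prior: NIWHyperparams = None,
) -> list[MixtureModel]:
    """Run the full finite-mixture Gibbs chain; returns post-burn-in, thinned
    posterior draws as MixtureModels.  Fully reproducible given config.seed."""
    if data.n_events < config.n_components:
        raise ValueError(
            f"need at least K={config.n_components} events, got {data.n_events}"
        )
    if prior is None:
        prior = default_hyperparams(data)
    rng = as_rng(config.seed)
    state = _initial_state(data, config, rng)
    draws: list[MixtureModel] = []
    for it in range(config.n_iterations):
        state = sample_indicators(data, state, rng)
        state = sample_weights(state, prior, rng)
        state = sample_component_params(data, state, prior, rng)
        state.iteration = it + 1
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            draws.append(state.mixture(data.channel_names))
    return draws
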