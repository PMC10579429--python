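"""Posterior sampling of the target mixture from noise and total-signal data.

The measurement model is C = T + xi with independent target T and
autofluorescence xi.  The posterior factorizes approximately into a noise
subproblem -- fitted from the noise data alone with the plain mixture
samplers -- and a target subproblem conditioned on a stored noise draw.  Each
cell of the total-signal table carries a latent pair label (noise component
j, target component k); the pair likelihood is N(c | mu_j + mu_k^T,
Sigma_j + Sigma_k^T).  The target covariance conditional has no exact closed
form, so the convolved precision is linearized around the effective expected
pair covariance Sigma_hat_jk, yielding a per-pair correction factor
(I - tau_hat_jk Sigma_j^xi) applied when the per-pair inverse-Wishart scales
are aggregated.  When that approximation overshoots, the offending matrices
are projected back onto the SPD cone and the projection count is surfaced in
the chain diagnostics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from ._utils import as_rng, chol_with_jitter, nearest_spd
from .conjugate import (
    ComponentStats,
    NIWHyperparams,
    default_hyperparams,
    posterior_predictive_logpdf,
)
from .events import EventTable
from .finite import (
    ChainConfig,
    categorical_rows,
    component_log_likelihoods,
    group_stats,
    run_finite_chain,
)
from .infinite import run_infinite_chain
from .mixture import MixtureModel, convolve_mixtures
from scipy.stats import invwishart

__all__ = [
    "ConvolvedSamplerState",
    "DeconvolutionPosterior",
    "fit_noise",
    "effective_covariance_hat",
    "sample_pair_indicators",
    "sample_target_weights",
    "sample_target_covariance",
    "sample_target_mean",
    "default_target_prior",
    "run_deconvolution",
]


@dataclass
class ConvolvedSamplerState:
    """Per-cell pair labels (noise j, target k), per-pair statistics, the
    current target parameters and the active noise-posterior draw."""

    assignments: np.ndarray        # (N,) pair index p = j * K_T + k
    noise: MixtureModel
    target_weights: np.ndarray     # (K_T,)
    target_means: np.ndarray       # (K_T, d)
    target_covs: np.ndarray        # (K_T, d, d)
    pair_ns: np.ndarray            # (K_xi, K_T)
    pair_means: np.ndarray         # (K_xi, K_T, d)
    pair_scatters: np.ndarray      # (K_xi, K_T, d, d)
    iteration: int = 0
    diagnostics: dict = field(default_factory=lambda: {"spd_clips": 0})

    @property
    def n_target(self) -> int:
        return self.target_weights.shape[0]

    @property
    def n_noise(self) -> int:
        return self.noise.n_components

    @property
    def target_counts(self) -> np.ndarray:
        """n_k^T: pair counts summed over the noise label."""
        return self.pair_ns.sum(axis=0)

    def target_mixture(self, channel_names=None) -> MixtureModel:
        w = self.target_weights / self.target_weights.sum()
        return MixtureModel.from_arrays(
            w, self.target_means, self.target_covs, channel_names
        )


def effective_covariance_hat(
    pair_stats: ComponentStats, prior: NIWHyperparams
) -> np.ndarray:
    """Effective expected covariance of one (noise, target) pair.

    This is the posterior-expected convolved covariance given the pair's
    data: the conditional inverse-Wishart scale
    n S2 + kappa0 (x_bar - mu0)(x_bar - mu0)' + Sigma0 divided by its mean
    denominator (n + nu0 - p), so that Sigma_hat approximates
    Sigma^xi + Sigma^T on covariance scale.  Its inverse tau_hat enters the
    correction factor (I - tau_hat Sigma^xi) that transfers the
    convolved-covariance conditional onto the target covariance alone; an
    un-normalized sum-of-squares here would make the correction vanish as
    n grows and the variance would never deconvolve."""
    diff = pair_stats.mean - prior.mu0
    p = prior.dimension
    denom = max(pair_stats.n + prior.nu0 - p, 1.0)
    return (
        pair_stats.n * pair_stats.scatter
        + prior.kappa0 * np.outer(diff, diff)
        + prior.sigma0
    ) / denom


def _pair_params(state: ConvolvedSamplerState):
    """Stacked means/covs/log-weights of all K_xi * K_T convolved pairs."""
    noise = state.noise
    kxi, kt = state.n_noise, state.n_target
    d = state.target_means.shape[1]
    means = (
        noise.means[:, None, :] + state.target_means[None, :, :]
    ).reshape(kxi * kt, d)
    covs = (
        noise.covariances[:, None, :, :] + state.target_covs[None, :, :, :]
    ).reshape(kxi * kt, d, d)
    logw = (
        np.log(np.maximum(noise.weights, 1e-300))[:, None]
        + np.log(np.maximum(state.target_weights, 1e-300))[None, :]
    ).reshape(kxi * kt)
    return means, covs, logw


def _pair_stats(values: np.ndarray, labels: np.ndarray, kxi: int, kt: int):
    ns, means, scatters = group_stats(values, labels, kxi * kt)
    d = values.shape[1]
    return (
        ns.reshape(kxi, kt),
        means.reshape(kxi, kt, d),
        scatters.reshape(kxi, kt, d, d),
    )


def sample_pair_indicators(
    conv_data: EventTable, state: ConvolvedSamplerState, seed=None
) -> ConvolvedSamplerState:
    """Draw each cell's (j, k) pair with probability proportional to
    omega_j^xi omega_k^T N(c_i | mu_j^xi + mu_k^T, Sigma_j^xi + Sigma_k^T),
    then refresh the per-pair statistics."""
    rng = as_rng(seed)
    means, covs, logw = _pair_params(state)
    logs = component_log_likelihoods(conv_data.values, means, covs) + logw
    labels = categorical_rows(logs, rng)
    ns, mus, scs = _pair_stats(
        conv_data.values, labels, state.n_noise, state.n_target
    )
    return replace(
        state, assignments=labels, pair_ns=ns, pair_means=mus, pair_scatters=scs
    )


def sample_target_weights(
    state: ConvolvedSamplerState, prior: NIWHyperparams, seed=None
) -> ConvolvedSamplerState:
    """omega^T ~ Dirichlet(n^T + alpha/K_T) with n_k^T = sum_j n_jk."""
    rng = as_rng(seed)
    conc = state.target_counts + prior.alpha / state.n_target
    return replace(state, target_weights=rng.dirichlet(conc))


def sample_target_covariance(
    state: ConvolvedSamplerState,
    prior: NIWHyperparams,
    seed=None,
    normalize_prior: bool = False,
) -> ConvolvedSamplerState:
    """Per target component: build the per-pair inverse-Wishart scale,
    apply the correction factor (I - tau_hat_jk Sigma_j^xi), aggregate over
    noise components, symmetrize, and draw Sigma_k^T ~ InvW(scale, n_k+nu0+1).

    With ``normalize_prior`` the kappa0/mu0/Sigma0 terms inside the per-pair
    sum are divided by K_xi so the prior is counted once rather than once per
    noise component (the per-pair form counts it K_xi times)."""
    rng = as_rng(seed)
    kxi, kt = state.n_noise, state.n_target
    d = state.target_means.shape[1]
    noise = state.noise
    prior_div = kxi if normalize_prior else 1.0
    covs = state.target_covs.copy()
    clips = 0
    eye = np.eye(d)
    for k in range(kt):
        mu_t = state.target_means[k]
        agg = np.zeros((d, d))
        dprior = mu_t - prior.mu0
        prior_term = (
            prior.kappa0 * np.outer(dprior, dprior) + prior.sigma0
        ) / prior_div
        for j in range(kxi):
            n_jk = state.pair_ns[j, k]
            sig_xi = noise.components[j].covariance
            dmean = state.pair_means[j, k] - noise.components[j].mean - mu_t
            scale_jk = (
                n_jk * state.pair_scatters[j, k]
                + n_jk * np.outer(dmean, dmean)
                + prior_term
            )
            st = ComponentStats(
                int(n_jk), state.pair_means[j, k], state.pair_scatters[j, k]
            )
            sigma_hat = effective_covariance_hat(st, prior)
            corr = eye - np.linalg.solve(sigma_hat, sig_xi)
            corr, clipped = nearest_spd(corr)
            clips += clipped
            agg += scale_jk @ corr
        agg, clipped = nearest_spd(agg)
        clips += clipped
        # the scale can never drop below the prior contribution: in the
        # noise-free conditional Sigma0 enters additively and unshrunk, and
        # without this floor a clipped-to-zero correction factor (noise
        # covariance comparable to the pair covariance) lets components
        # collapse to point masses
        diff = agg - prior.sigma0
        vals, vecs = np.linalg.eigh(0.5 * (diff + diff.T))
        if vals[0] < 0:
            clips += 1
            agg = prior.sigma0 + (vecs * np.maximum(vals, 0.0)) @ vecs.T
        df = state.target_counts[k] + prior.nu0 + 1
        covs[k] = np.atleast_2d(
            invwishart.rvs(df=df, scale=agg, random_state=rng)
        )
    diagnostics = dict(state.diagnostics)
    diagnostics["spd_clips"] = diagnostics.get("spd_clips", 0) + clips
    return replace(state, target_covs=covs, diagnostics=diagnostics)


def sample_target_mean(
    state: ConvolvedSamplerState,
    prior: NIWHyperparams,
    seed=None,
    normalize_prior: bool = False,
) -> ConvolvedSamplerState:
    """mu_k^T ~ N(mu_tilde_k, tau_tilde_k^-1) with
    tau_tilde_k = sum_j (n_jk + kappa0)(Sigma_j^xi + Sigma_k^T)^-1 and
    mu_tilde_k = tau_tilde_k^-1 sum_j (Sigma_j^xi + Sigma_k^T)^-1
    (n_jk x_bar_jk + kappa0 mu0)."""
    rng = as_rng(seed)
    kxi, kt = state.n_noise, state.n_target
    d = state.target_means.shape[1]
    noise = state.noise
    k0 = prior.kappa0 / (kxi if normalize_prior else 1.0)
    means = state.target_means.copy()
    for k in range(kt):
        tau = np.zeros((d, d))
        vec = np.zeros(d)
        for j in range(kxi):
            prec = np.linalg.inv(
                noise.components[j].covariance + state.target_covs[k]
            )
            n_jk = state.pair_ns[j, k]
            tau += (n_jk + k0) * prec
            vec += prec @ (n_jk * state.pair_means[j, k] + k0 * prior.mu0)
        cov = np.linalg.inv(tau)
        cov = 0.5 * (cov + cov.T)
        mu_tilde = cov @ vec
        means[k] = mu_tilde + chol_with_jitter(cov) @ rng.standard_normal(d)
    return replace(state, target_means=means)


def fit_noise(
    noise_data: EventTable,
    config: ChainConfig,
    prior: NIWHyperparams = None,
    model: str = "finite",
) -> list[MixtureModel]:
    """Posterior draws of the noise mixture from the noise data alone."""
    if noise_data.n_events < 1:
        raise ValueError("noise data are empty")
    if model == "finite":
        return run_finite_chain(noise_data, config, prior)
    if model == "infinite":
        return run_infinite_chain(noise_data, config, prior)
    raise ValueError("model must be 'finite' or 'infinite'")


def default_target_prior(
    conv_data: EventTable,
    noise_data: EventTable,
    alpha: float = 1.0,
    kappa0: float = 1.0,
    nu0: float = None,
) -> NIWHyperparams:
    """Target prior from the moment difference between the two tables.

    mu0 = mean(conv) - mean(noise); Sigma0 = cov(conv) - cov(noise), with its
    eigenvalues floored so Sigma0 stays above 10% of the convolved covariance
    (the difference can be indefinite in small samples).  The rationale is
    that the prior should sit where the target density lies, and the target is
    shifted and narrowed relative to the convolved data.
    """
    xc, xn = conv_data.values, noise_data.values
    mu0 = xc.mean(axis=0) - xn.mean(axis=0)
    dc = xc - xc.mean(axis=0)
    dn = xn - xn.mean(axis=0)
    cov_c = dc.T @ dc / xc.shape[0]
    cov_n = dn.T @ dn / xn.shape[0]
    floor = 0.1 * cov_c
    diff = cov_c - cov_n - floor
    vals, vecs = np.linalg.eigh(0.5 * (diff + diff.T))
    sigma0 = floor + (vecs * np.maximum(vals, 0.0)) @ vecs.T
    d = conv_data.dimension
    if nu0 is None:
        nu0 = d + 2
    return NIWHyperparams(mu0=mu0, kappa0=kappa0, sigma0=sigma0, nu0=nu0,
                          alpha=alpha)


@dataclass
class DeconvolutionPosterior:
    """Paired posterior draws of the noise and target mixtures.

    ``noise_draws[i]`` is the noise draw that conditioned ``target_draws[i]``.
    Density-level summaries (averaged pdf, pointwise credible bands) are the
    supported outputs; individual components are not identifiable across
    draws (label switching is not corrected).
    """

    noise_draws: list[MixtureModel]
    target_draws: list[MixtureModel]
    diagnostics: dict = field(default_factory=dict)
    channel_names: list[str] = None

    def convolved_draws(self) -> list[MixtureModel]:
        return [
            convolve_mixtures(t, n)
            for t, n in zip(self.target_draws, self.noise_draws)
        ]

    def _draw_pdfs(self, points: np.ndarray) -> np.ndarray:
        d = self.target_draws[0].dimension
        pts = np.asarray(points, dtype=float).reshape(-1, d)
        return np.stack(
            [m.pdf(pts if d > 1 else pts[:, 0]) for m in self.target_draws]
        )

    def target_mean_density(self, points) -> np.ndarray:
        return self._draw_pdfs(points).mean(axis=0)

    def credible_band(self, points, lower: float = 0.05, upper: float = 0.95):
        vals = self._draw_pdfs(points)
        return (
            np.quantile(vals, lower, axis=0),
            np.quantile(vals, upper, axis=0),
        )

    def summary_table(self, points):
        """Grid, posterior-mean density and 5%/95% bands as a dict of arrays."""
        points = np.asarray(points, dtype=float)
        lo, hi = self.credible_band(points)
        return {
            "grid": points.reshape(points.shape[0], -1),
            "mean_density": self.target_mean_density(points),
            "band_low": lo,
            "band_high": hi,
        }

    def to_dict(self) -> dict:
        return {
            "channel_names": self.channel_names,
            "diagnostics": self.diagnostics,
            "noise_draws": [m.to_dict() for m in self.noise_draws],
            "target_draws": [m.to_dict() for m in self.target_draws],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DeconvolutionPosterior":
        return cls(
            noise_draws=[MixtureModel.from_dict(m) for m in payload["noise_draws"]],
            target_draws=[MixtureModel.from_dict(m) for m in payload["target_draws"]],
            diagnostics=payload.get("diagnostics", {}),
            channel_names=payload.get("channel_names"),
        )


def _initial_target(
    conv_data: EventTable,
    noise: MixtureModel,
    kt: int,
    prior: NIWHyperparams,
    rng: np.random.Generator,
):
    """k-means the convolved data into K_T groups, subtract the noise moments
    and floor the covariances; degenerate groups fall back to the prior."""
    x = conv_data.values
    d = x.shape[1]
    if kt > 1 and x.shape[0] >= kt:
        km = KMeans(n_clusters=kt, n_init=1,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(x)
    else:
        labels = rng.integers(kt, size=x.shape[0])
    ns, means, scatters = group_stats(x, labels, kt)
    noise_mean = noise.mean()
    noise_cov = noise.covariance()
    t_means = means - noise_mean
    t_covs = np.empty((kt, d, d))
    for k in range(kt):
        if ns[k] < 2:
            t_means[k] = prior.mu0
            t_covs[k] = prior.sigma0
            continue
        diff = scatters[k] - noise_cov - 0.1 * scatters[k]
        vals, vecs = np.linalg.eigh(0.5 * (diff + diff.T))
        t_covs[k] = 0.1 * scatters[k] + (vecs * np.maximum(vals, 0.0)) @ vecs.T
    w = np.maximum(ns, 1.0)
    return w / w.sum(), t_means, t_covs


def run_deconvolution(
    noise_data: EventTable,
    conv_data: EventTable,
    config_noise: ChainConfig = None,
    config_target: ChainConfig = None,
    prior_noise: NIWHyperparams = None,
    prior_target: NIWHyperparams = None,
    noise_model: str = "finite",
    target_model: str = "finite",
    noise_refresh: str = "cycle",
    normalize_prior: bool = False,
    noise_draws: list[MixtureModel] = None,
) -> DeconvolutionPosterior:
    """Full two-stage deconvolution.

    Stage one fits the noise mixture on the noise table alone; stage two runs
    the convolved Gibbs loop on the total-signal table, refreshing the active
    noise draw from the stored noise posterior each iteration (cycled in
    order by default, uniformly resampled with ``noise_refresh="resample"``).
    ``noise_draws`` short-circuits stage one with precomputed draws.
    """
    if noise_data.dimension != conv_data.dimension:
        raise ValueError(
            f"noise table has d={noise_data.dimension} but total-signal table "
            f"has d={conv_data.dimension}"
        )
    config_noise = config_noise or ChainConfig()
    config_target = config_target or ChainConfig()
    if prior_noise is None:
        prior_noise = default_hyperparams(noise_data)
    if prior_target is None:
        prior_target = default_target_prior(conv_data, noise_data)
    if noise_draws is None:
        noise_draws = fit_noise(noise_data, config_noise, prior_noise,
                                model=noise_model)
    if not noise_draws:
        raise ValueError("noise posterior contains no draws")
    rng = as_rng(config_target.seed)
    if target_model == "infinite":
        return _run_infinite_target(
            conv_data, noise_draws, config_target, prior_target, rng,
            noise_refresh,
        )
    kt = config_target.n_components
    noise0 = noise_draws[0]
    w, mu, cov = _initial_target(conv_data, noise0, kt, prior_target, rng)
    kxi = noise0.n_components
    d = conv_data.dimension
    state = ConvolvedSamplerState(
        assignments=np.zeros(conv_data.n_events, dtype=int),
        noise=noise0,
        target_weights=w,
        target_means=mu,
        target_covs=cov,
        pair_ns=np.zeros((kxi, kt)),
        pair_means=np.zeros((kxi, kt, d)),
        pair_scatters=np.zeros((kxi, kt, d, d)),
    )
    state = sample_pair_indicators(conv_data, state, rng)
    kept_t: list[MixtureModel] = []
    kept_n: list[MixtureModel] = []
    m = len(noise_draws)
    for it in range(config_target.n_iterations):
        if noise_refresh == "resample":
            noise = noise_draws[int(rng.integers(m))]
        else:
            noise = noise_draws[it % m]
        if noise.n_components != state.n_noise:
            # active noise draw changed size (infinite noise model): reshape
            # the pair bookkeeping and re-sample the indicators
            kxi = noise.n_components
            state = replace(
                state,
                noise=noise,
                pair_ns=np.zeros((kxi, kt)),
                pair_means=np.zeros((kxi, kt, d)),
                pair_scatters=np.zeros((kxi, kt, d, d)),
            )
        else:
            state = replace(state, noise=noise)
        state = sample_pair_indicators(conv_data, state, rng)
        state = sample_target_weights(state, prior_target, rng)
        state = sample_target_covariance(
            state, prior_target, rng, normalize_prior=normalize_prior
        )
        state = sample_target_mean(
            state, prior_target, rng, normalize_prior=normalize_prior
        )
        state.iteration = it + 1
        if it >= config_target.burn_in and (
            it - config_target.burn_in
        ) % config_target.thin == 0:
            kept_t.append(state.target_mixture(conv_data.channel_names))
            kept_n.append(noise)
    return DeconvolutionPosterior(
        noise_draws=kept_n,
        target_draws=kept_t,
        diagnostics=dict(state.diagnostics),
        channel_names=list(conv_data.channel_names),
    )


# --------------------------------------------------------------------------
# infinite-target extension: CRP over target labels with the noise label
# resampled jointly per cell
# --------------------------------------------------------------------------

def _run_infinite_target(
    conv_data, noise_draws, config, prior, rng, noise_refresh
) -> DeconvolutionPosterior:
    """Dirichlet-process variant of the convolved sampler.

    Cells are reseated sequentially over (noise component, target component)
    pairs: occupied target components attract with weight proportional to
    their count times the convolved normal likelihood, a new target component
    opens with weight alpha times the prior-predictive density of the
    noise-residual c_i - mu_j^xi.  Parameter draws reuse the finite convolved
    conditionals over the active set.  Provided as an extension; the finite
    variant is the benchmarked path.
    """
    x = conv_data.values
    n, d = x.shape
    noise0 = noise_draws[0]
    # start from a single target component at the residual moments
    mu_init = x.mean(axis=0) - noise0.mean()
    labels_k = np.zeros(n, dtype=int)
    labels_j = np.zeros(n, dtype=int)
    t_means = mu_init[None, :].copy()
    t_covs = prior.sigma0[None, :, :].copy()
    t_weights = np.array([1.0])
    kept_t, kept_n = [], []
    m = len(noise_draws)
    diagnostics = {"spd_clips": 0}
    empty = ComponentStats.empty(d)
    for it in range(config.n_iterations):
        noise = (
            noise_draws[int(rng.integers(m))]
            if noise_refresh == "resample"
            else noise_draws[it % m]
        )
        kxi = noise.n_components
        logw_xi = np.log(np.maximum(noise.weights, 1e-300))
        counts = np.bincount(labels_k, minlength=t_means.shape[0]).astype(float)
        for i in range(n):
            counts[labels_k[i]] -= 1.0
        # (reseat sequentially)
            kt = t_means.shape[0]
            logs = np.empty(kxi * kt + kxi)
            for j in range(kxi):
                mu_j = noise.components[j].mean
                cov_j = noise.components[j].covariance
                for k in range(kt):
                    if counts[k] <= 0:
                        logs[j * kt + k] = -np.inf
                        continue
                    cov = cov_j + t_covs[k]
                    L = chol_with_jitter(cov, warn=False)
                    sol = np.linalg.solve(L, x[i] - mu_j - t_means[k])
                    logs[j * kt + k] = (
                        logw_xi[j]
                        + math.log(counts[k] / (n + prior.alpha - 1.0))
                        - np.sum(np.log(np.diag(L)))
                        - 0.5 * d * math.log(2 * math.pi)
                        - 0.5 * np.dot(sol, sol)
                    )
                pred_new = np.asarray(
                    posterior_predictive_logpdf(x[i] - mu_j, empty, prior)
                ).reshape(-1)[0]
                logs[kxi * kt + j] = (
                    logw_xi[j]
                    + math.log(prior.alpha / (n + prior.alpha - 1.0))
                    + pred_new
                )
            mx = logs.max()
            p = np.exp(logs - mx)
            choice = int(np.searchsorted(np.cumsum(p), rng.random() * p.sum(),
                                         side="right"))
            if choice >= kxi * kt:
                j_new, k_new = choice - kxi * kt, kt
                cov_new = np.atleast_2d(
                    invwishart.rvs(df=prior.nu0 + 1, scale=prior.sigma0,
                                   random_state=rng)
                )
                mu_new = prior.mu0 + chol_with_jitter(
                    cov_new / prior.kappa0
                ) @ rng.standard_normal(d)
                t_means = np.vstack([t_means, mu_new[None, :]])
                t_covs = np.concatenate([t_covs, cov_new[None, :, :]])
                counts = np.append(counts, 0.0)
            else:
                j_new, k_new = divmod(choice, kt)
            labels_j[i], labels_k[i] = j_new, k_new
            counts[k_new] += 1.0
        # drop empty target components and relabel
        active = np.where(counts > 0)[0]
        remap = -np.ones(counts.shape[0], dtype=int)
        remap[active] = np.arange(active.shape[0])
        labels_k = remap[labels_k]
        t_means, t_covs = t_means[active], t_covs[active]
        kt = active.shape[0]
        # parameter draws via the finite convolved conditionals
        pair_labels = labels_j * kt + labels_k
        ns, mus, scs = _pair_stats(x, pair_labels, kxi, kt)
        state = ConvolvedSamplerState(
            assignments=pair_labels,
            noise=noise,
            target_weights=np.full(kt, 1.0 / kt),
            target_means=t_means,
            target_covs=t_covs,
            pair_ns=ns,
            pair_means=mus,
            pair_scatters=scs,
            diagnostics=diagnostics,
        )
        state = replace(
            state, target_weights=rng.dirichlet(state.target_counts + prior.alpha)
        )
        state = sample_target_covariance(state, prior, rng)
        state = sample_target_mean(state, prior, rng)
        t_means, t_covs = state.target_means, state.target_covs
        t_weights = state.target_weights
        diagnostics = state.diagnostics
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept_t.append(state.target_mixture(conv_data.channel_names))
            kept_n.append(noise)
    return DeconvolutionPosterior(
        noise_draws=kept_n,
        target_draws=kept_t,
        diagnostics=diagnostics,
        channel_names=list(conv_data.channel_names),
    )
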