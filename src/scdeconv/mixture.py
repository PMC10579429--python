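"""Gaussian mixture models and the Gaussian convolution identity.

The additive measurement model C = T + xi implies that the density of the
total signal is the convolution p_C = p_T * p_xi.  When both densities are
normal mixtures the convolution is again a normal mixture whose components
combine pairwise: weights multiply, means and covariances add.  That identity
(`convolve_mixtures`) is what makes the convolved Gibbs sampler tractable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from ._utils import LOG_2PI, as_rng, chol_with_jitter
from .events import EventTable

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "mixture_logpdf",
    "sample_mixture",
    "convolve_mixtures",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture basis: weight, mean vector and covariance matrix."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        w = float(self.weight)
        if not 0.0 <= w <= 1.0 + 1e-12:
            raise ValueError(f"component weight {w} outside [0, 1]")
        object.__setattr__(self, "weight", w)
        d = mean.shape[0]
        if cov.shape != (d, d):
            raise ValueError(f"covariance shape {cov.shape} incompatible with d={d}")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        # positive definiteness is the contract: Cholesky must succeed
        np.linalg.cholesky(cov + 0.0)

    @property
    def dimension(self) -> int:
        return self.mean.shape[0]


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x | mean, cov) for x of shape (n, d); returns shape (n,)."""
    L = chol_with_jitter(cov)
    diff = x - mean
    sol = solve_triangular(L, diff.T, lower=True)
    quad = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (mean.shape[0] * LOG_2PI + logdet + quad)


@dataclass
class MixtureModel:
    """Ordered set of Gaussian components over d channels.

    Component weights must sum to one (within 1e-12) and all components must
    share the same dimension.
    """

    components: list[GaussianComponent]
    channel_names: list[str] = field(default=None)

    def __post_init__(self):
        if not self.components:
            raise ValueError("mixture needs at least one component")
        d = self.components[0].dimension
        for c in self.components:
            if c.dimension != d:
                raise ValueError("components have inconsistent dimensions")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"component weights sum to {total!r}, not 1")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(d)]
        elif len(self.channel_names) != d:
            raise ValueError("channel_names length must equal dimension")

    @property
    def dimension(self) -> int:
        return self.components[0].dimension

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.covariance for c in self.components])

    def logpdf(self, x) -> np.ndarray:
        return mixture_logpdf(x, self)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def sample(self, n: int, seed=None) -> EventTable:
        return sample_mixture(self, n, seed)

    def mean(self) -> np.ndarray:
        """Mixture mean: sum of weighted component means."""
        return np.einsum("k,kd->d", self.weights, self.means)

    def covariance(self) -> np.ndarray:
        """Mixture covariance (within- plus between-component parts)."""
        m = self.mean()
        w, mu, cov = self.weights, self.means, self.covariances
        between = np.einsum("k,kd,ke->de", w, mu - m, mu - m)
        return np.einsum("k,kde->de", w, cov) + between

    # -- JSON layout: {dimension, channel_names, components:[{weight, mean,
    #    covariance(row-major)}]}; lossless at full double precision ----------
    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "channel_names": list(self.channel_names),
            "components": [
                {
                    "weight": c.weight,
                    "mean": c.mean.tolist(),
                    "covariance": c.covariance.reshape(-1).tolist(),
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureModel":
        d = int(payload["dimension"])
        comps = [
            GaussianComponent(
                weight=c["weight"],
                mean=np.asarray(c["mean"], dtype=float),
                covariance=np.asarray(c["covariance"], dtype=float).reshape(d, d),
            )
            for c in payload["components"]
        ]
        return cls(comps, payload.get("channel_names"))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "MixtureModel":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_arrays(cls, weights, means, covariances, channel_names=None):
        weights = np.asarray(weights, dtype=float)
        means = np.atleast_2d(np.asarray(means, dtype=float))
        covariances = np.asarray(covariances, dtype=float)
        if means.shape[0] != weights.shape[0]:
            means = means.T
        comps = [
            GaussianComponent(w, m, c)
            for w, m, c in zip(weights, means, covariances)
        ]
        return cls(comps, channel_names)

    def window(self) -> tuple[np.ndarray, np.ndarray]:
        """Evaluation window: union of mean +/- 8 sigma over components."""
        sds = np.sqrt(np.stack([np.diag(c.covariance) for c in self.components]))
        mus = self.means
        return (mus - 8.0 * sds).min(axis=0), (mus + 8.0 * sds).max(axis=0)


def _as_points(x, d: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    scalar = False
    if x.ndim == 0:
        x = x.reshape(1, 1)
        scalar = True
    elif x.ndim == 1:
        if d == 1:
            x = x.reshape(-1, 1)
        else:
            x = x.reshape(1, -1)
            scalar = True
    if x.shape[1] != d:
        raise ValueError(f"points have dimension {x.shape[1]}, mixture expects {d}")
    return x, scalar


def mixture_logpdf(x, model: MixtureModel) -> np.ndarray:
    """Stable log-density of the mixture at ``x`` via log-sum-exp.

    ``x`` may be a scalar (d=1), a length-d vector, or an (n, d) array.
    """
    pts, scalar = _as_points(x, model.dimension)
    logs = np.empty((pts.shape[0], model.n_components))
    logw = np.log(np.maximum(model.weights, 1e-300))
    for k, comp in enumerate(model.components):
        logs[:, k] = logw[k] + _gauss_logpdf(pts, comp.mean, comp.covariance)
    out = logsumexp(logs, axis=1)
    return float(out[0]) if scalar else out


def sample_mixture(model: MixtureModel, n: int, seed=None) -> EventTable:
    """Draw ``n`` events: component index from the weights, then a normal draw."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = as_rng(seed)
    labels = rng.choice(model.n_components, size=n, p=model.weights)
    out = np.empty((n, model.dimension))
    z = rng.standard_normal((n, model.dimension))
    for k, comp in enumerate(model.components):
        mask = labels == k
        if not np.any(mask):
            continue
        L = chol_with_jitter(comp.covariance)
        out[mask] = comp.mean + z[mask] @ L.T
    return EventTable(out, list(model.channel_names))


def convolve_mixtures(target: MixtureModel, noise: MixtureModel) -> MixtureModel:
    """Mixture of the sum of independent mixture variables.

    The K_T * K_xi output components have weights w_i^T w_j^xi, means
    mu_i^T + mu_j^xi and covariances Sigma_i^T + Sigma_j^xi; the output weights
    again sum to one.
    """
    if target.dimension != noise.dimension:
        raise ValueError(
            f"dimension mismatch: target d={target.dimension}, "
            f"noise d={noise.dimension}"
        )
    comps = [
        GaussianComponent(
            t.weight * s.weight, t.mean + s.mean, t.covariance + s.covariance
        )
        for t in target.components
        for s in noise.components
    ]
    # renormalize away accumulated rounding in the weight products
    total = sum(c.weight for c in comps)
    comps = [
        GaussianComponent(c.weight / total, c.mean, c.covariance) for c in comps
    ]
    return MixtureModel(comps, list(target.channel_names))
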