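import numpy as np
import pytest

from scdeconv import (
    ChainConfig,
    EventTable,
    GaussianComponent,
    MixtureModel,
    NIWHyperparams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def std_normal_1d():
    return MixtureModel([GaussianComponent(1.0, [0.0], [[1.0]])])


@pytest.fixture
def bimodal_target():
    """Worked-example target: 0.8 N(-0.43, 0.6^2) + 0.2 N(1.67, 0.6^2)."""
    return MixtureModel(
        [
            GaussianComponent(0.8, [-0.43], [[0.36]]),
            GaussianComponent(0.2, [1.67], [[0.36]]),
        ]
    )


@pytest.fixture
def narrow_noise():
    return MixtureModel([GaussianComponent(1.0, [0.0], [[0.25]])])


@pytest.fixture
def flat_prior_1d():
    return NIWHyperparams(mu0=[0.0], kappa0=1.0, sigma0=[[1.0]], nu0=3.0,
                          alpha=1.0)


def random_mixture(rng, d=1, k=2, spread=2.0):
    """Helper shared across tests: a random valid mixture."""
    weights = rng.dirichlet(np.ones(k) * 2.0)
    means = rng.normal(0.0, spread, size=(k, d))
    covs = []
    for _ in range(k):
        a = rng.normal(size=(d, d))
        covs.append(a @ a.T + 0.3 * np.eye(d))
    return MixtureModel(
        [GaussianComponent(w, m, c) for w, m, c in zip(weights, means, covs)]
    )
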