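"""Convolved Gibbs sampler: pair indicators, target conditionals, pipeline."""
import numpy as np
import pytest
from scipy import stats as sps

from scdeconv import (
    ChainConfig,
    ComponentStats,
    EventTable,
    GaussianComponent,
    MixtureModel,
    NIWHyperparams,
    convolve_mixtures,
    effective_covariance_hat,
    fit_noise,
    run_deconvolution,
    run_finite_chain,
)
from scdeconv.deconvolve import (
    ConvolvedSamplerState,
    DeconvolutionPosterior,
    _pair_stats,
    default_target_prior,
    sample_pair_indicators,
    sample_target_covariance,
    sample_target_mean,
    sample_target_weights,
)
from scdeconv.metrics import posterior_mio
from scdeconv.synthetic import demo_dataset, demo_noise, demo_target


def build_state(conv_values, noise, t_weights, t_means, t_covs):
    kxi, kt = noise.n_components, len(t_weights)
    d = conv_values.shape[1]
    state = ConvolvedSamplerState(
        assignments=np.zeros(conv_values.shape[0], dtype=int),
        noise=noise,
        target_weights=np.asarray(t_weights, float),
        target_means=np.asarray(t_means, float).reshape(kt, d),
        target_covs=np.asarray(t_covs, float).reshape(kt, d, d),
        pair_ns=np.zeros((kxi, kt)),
        pair_means=np.zeros((kxi, kt, d)),
        pair_scatters=np.zeros((kxi, kt, d, d)),
    )
    return sample_pair_indicators(EventTable(conv_values), state,
                                  np.random.default_rng(0))


class TestEffectiveCovariance:
    def test_empty_pair_reduces_to_scaled_prior(self, flat_prior_1d):
        got = effective_covariance_hat(ComponentStats.empty(1), flat_prior_1d)
        # prior-only posterior-expected covariance: Sigma0 / (nu0 - p)
        assert got[0, 0] == pytest.approx(1.0 / 2.0)

    def test_posterior_mean_formula(self, flat_prior_1d):
        stats = ComponentStats(10, np.array([0.0]), np.array([[1.0]]))
        got = effective_covariance_hat(stats, flat_prior_1d)
        assert got[0, 0] == pytest.approx((10 * 1.0 + 1.0) / (10 + 3 - 1))

    def test_estimates_the_convolved_variance(self, flat_prior_1d, rng):
        x = rng.normal(0.0, np.sqrt(0.61), size=(4000, 1))
        got = effective_covariance_hat(ComponentStats.from_data(x),
                                       flat_prior_1d)
        assert got[0, 0] == pytest.approx(0.61, rel=0.1)

    def test_correction_factor_tends_to_identity_without_noise(
            self, flat_prior_1d):
        stats = ComponentStats(50, np.array([0.0]), np.array([[0.5]]))
        hat = effective_covariance_hat(stats, flat_prior_1d)
        for sig_xi in (1e-3, 1e-6, 1e-9):
            corr = 1.0 - sig_xi / hat[0, 0]
            assert corr == pytest.approx(1.0, abs=sig_xi * 10)


class TestPairIndicators:
    def test_single_pair_takes_all_cells(self, rng):
        noise = demo_noise()
        state = build_state(rng.normal(size=(100, 1)), noise, [1.0], [[0.0]],
                            [[[1.0]]])
        assert np.all(state.assignments == 0)
        assert state.pair_ns[0, 0] == 100

    def test_identical_targets_split_symmetrically(self, rng):
        noise = demo_noise()
        state = build_state(
            rng.normal(size=(20000, 1)), noise,
            [0.5, 0.5], [[0.0], [0.0]], [[[1.0]], [[1.0]]],
        )
        frac = state.pair_ns[0, 0] / 20000
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_tiny_noise_matches_plain_responsibilities(self, rng):
        """With point-mass noise the pair assignment reduces to the ordinary
        finite-mixture responsibilities of the data."""
        x = np.concatenate([rng.normal(-3, 1, 500), rng.normal(3, 1, 500)])
        noise = MixtureModel([GaussianComponent(1.0, [0.0], [[1e-10]])])
        state = build_state(x.reshape(-1, 1), noise, [0.5, 0.5],
                            [[-3.0], [3.0]], [[[1.0]], [[1.0]]])
        # plain Bayes classifier at 0: only ~Phi(-3) mass misassigned
        labels = state.assignments % 2
        wrong = np.sum(labels[:500] == 1) + np.sum(labels[500:] == 0)
        assert wrong / 1000 < 0.01


class TestTargetConditionals:
    def test_counts_sum_over_noise_labels(self, flat_prior_1d):
        noise = MixtureModel(
            [
                GaussianComponent(0.5, [0.0], [[1.0]]),
                GaussianComponent(0.5, [0.0], [[1.0]]),
            ]
        )
        # pairs: (j=0,k=0):3, (j=1,k=0):2, (j=0,k=1):5 -> n^T = (5, 5)
        labels = np.array([0] * 3 + [2] * 2 + [1] * 5)  # pair p = j*K_T + k
        state = build_state(np.zeros((10, 1)), noise, [0.5, 0.5],
                            [[0.0], [0.0]], [[[1.0]], [[1.0]]])
        state.assignments = labels
        ns, mus, scs = _pair_stats(np.zeros((10, 1)), labels, 2, 2)
        state.pair_ns = ns
        assert np.array_equal(state.target_counts, [5, 5])

    def test_weights_follow_dirichlet_moments(self, flat_prior_1d, rng):
        noise = demo_noise()
        state = build_state(np.zeros((8, 1)), noise, [0.5, 0.5],
                            [[0.0], [0.0]], [[[1.0]], [[1.0]]])
        state.pair_ns = np.array([[3.0, 5.0]])
        m = 20000
        draws = np.stack(
            [sample_target_weights(state, flat_prior_1d, rng).target_weights
             for _ in range(m)]
        )
        assert draws[:, 0].mean() == pytest.approx(3.5 / 9.0, abs=0.005)

    def test_covariance_reduces_to_plain_conditional_without_noise(
            self, flat_prior_1d):
        """As Sigma^xi -> 0 the aggregated scale reduces to the plain
        mean-conditional inverse-Wishart (KS test against scipy)."""
        rng = np.random.default_rng(42)
        x = rng.normal(1.0, 1.2, size=(200, 1))
        noise = MixtureModel([GaussianComponent(1.0, [0.0], [[1e-14]])])
        state = build_state(x, noise, [1.0], [[1.0]], [[[1.44]]])
        draws = np.array([
            sample_target_covariance(state, flat_prior_1d, rng)
            .target_covs[0, 0, 0]
            for _ in range(4000)
        ])
        stats = ComponentStats.from_data(x)
        scale = (200 * stats.scatter[0, 0]
                 + 200 * (stats.mean[0] - 1.0) ** 2
                 + 1.0 * (1.0 - 0.0) ** 2 + 1.0)
        ref = sps.invgamma(a=(200 + 3 + 1) / 2.0, scale=scale / 2.0)
        assert sps.kstest(draws, ref.cdf).pvalue > 0.01

    def test_recovers_target_variance_under_known_noise(self):
        """Single noise x single target: posterior mean of Sigma^T within
        10% of the true 0.36 when the convolved variance is 0.61."""
        rng = np.random.default_rng(7)
        n = 10000
        c = rng.normal(-0.43, 0.6, size=(n, 1)) + rng.normal(
            0.0, 0.5, size=(n, 1))
        noise = demo_noise()
        prior = NIWHyperparams([-0.43], 1.0, [[0.36]], 3.0)
        state = build_state(c, noise, [1.0], [[-0.43]], [[[0.36]]])
        data = EventTable(c)
        sig_draws = []
        for _ in range(400):
            state = sample_pair_indicators(data, state, rng)
            state = sample_target_covariance(state, prior, rng)
            state = sample_target_mean(state, prior, rng)
            sig_draws.append(state.target_covs[0, 0, 0])
        assert np.mean(sig_draws[100:]) == pytest.approx(0.36, rel=0.10)

    def test_mean_reduction_single_noise_component(self, flat_prior_1d):
        """One zero-mean noise component: mu_tilde reduces to the familiar
        (n xbar + kappa0 mu0)/(n + kappa0) weighting."""
        rng = np.random.default_rng(8)
        x = np.full((10, 1), 1.0)
        noise = MixtureModel([GaussianComponent(1.0, [0.0], [[1e-12]])])
        state = build_state(x, noise, [1.0], [[1.0]], [[[1.0]]])
        draws = np.array([
            sample_target_mean(state, flat_prior_1d, rng).target_means[0, 0]
            for _ in range(20000)
        ])
        assert draws.mean() == pytest.approx(10.0 / 11.0, abs=0.01)

    def test_duplicated_noise_components_aggregate_the_prior(
            self, flat_prior_1d):
        """Two identical noise components behave like one with the kappa0
        term counted per component (the printed per-pair sum)."""
        rng = np.random.default_rng(9)
        x = np.full((10, 1), 1.0)
        tiny = 1e-12
        noise2 = MixtureModel(
            [
                GaussianComponent(0.5, [0.0], [[tiny]]),
                GaussianComponent(0.5, [0.0], [[tiny]]),
            ]
        )
        state = build_state(x, noise2, [1.0], [[1.0]], [[[1.0]]])
        draws = np.array([
            sample_target_mean(state, flat_prior_1d, rng).target_means[0, 0]
            for _ in range(20000)
        ])
        # kappa0 enters once per noise component: (n xbar + 2 k0 mu0)/(n + 2 k0)
        assert draws.mean() == pytest.approx(10.0 / 12.0, abs=0.01)


class TestPipeline:
    def test_noise_fit_recovers_noise_density(self):
        noise_truth = demo_noise()
        data = noise_truth.sample(10000, seed=12)
        cfg = ChainConfig(n_components=4, n_iterations=400, burn_in=200,
                          thin=5, seed=13)
        draws = fit_noise(data, cfg)
        assert posterior_mio(noise_truth, draws,
                             summary="average_density") >= 0.97

    def test_student_noise_fit_with_normal_basis(self):
        from scdeconv.synthetic import make_noise

        truth = make_noise("student_t")
        data = truth.sample(5000, seed=14)
        cfg = ChainConfig(n_components=4, n_iterations=400, burn_in=200,
                          thin=5, seed=15)
        draws = fit_noise(data, cfg)
        assert posterior_mio(truth, draws, summary="average_density") >= 0.9

    def test_empty_noise_data_rejected(self):
        with pytest.raises(ValueError):
            EventTable(np.empty((0, 1)))

    def test_deconvolution_beats_null_on_worked_example(self):
        ds = demo_dataset(n=4000, seed=16)
        cfg = ChainConfig(n_components=4, n_iterations=600, burn_in=300,
                          thin=5, seed=17)
        post = run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 cfg, cfg)
        deconv = posterior_mio(ds.target_truth, post.target_draws,
                               summary="average_density")
        null = posterior_mio(
            ds.target_truth,
            run_finite_chain(ds.convolved_samples, cfg),
            summary="average_density",
        )
        assert deconv > null

    def test_near_degenerate_noise_reduces_to_plain_fit(self):
        """Identity-noise limit: deconvolving with a vanishing noise source
        reproduces the plain finite fit of the same data."""
        truth = demo_target()
        conv = truth.sample(3000, seed=18)
        noise = EventTable(
            np.random.default_rng(19).normal(0, 1e-3, size=(3000, 1)))
        cfg = ChainConfig(n_components=4, n_iterations=500, burn_in=250,
                          thin=5, seed=20)
        post = run_deconvolution(noise, conv, cfg, cfg)
        plain = run_finite_chain(conv, cfg)
        xs = np.linspace(-4, 5, 2001)
        from scdeconv.metrics import DensityGrid, average_pdf, mio

        pair = DensityGrid(
            xs[:, None],
            average_pdf(plain, xs[:, None]),
            post.target_mean_density(xs[:, None]),
            np.gradient(xs),
        )
        assert mio(pair, None) >= 0.98

    def test_seeded_rerun_is_identical(self):
        ds = demo_dataset(n=500, seed=21)
        cfg = ChainConfig(n_components=3, n_iterations=80, burn_in=40,
                          thin=4, seed=22)
        a = run_deconvolution(ds.noise_samples, ds.convolved_samples, cfg, cfg)
        b = run_deconvolution(ds.noise_samples, ds.convolved_samples, cfg, cfg)
        for ma, mb in zip(a.target_draws, b.target_draws):
            assert np.array_equal(ma.means, mb.means)
            assert np.array_equal(ma.covariances, mb.covariances)

    def test_every_target_draw_is_a_valid_mixture(self):
        ds = demo_dataset(n=800, seed=23)
        cfg = ChainConfig(n_components=4, n_iterations=120, burn_in=60,
                          thin=3, seed=24)
        post = run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 cfg, cfg)
        for m in post.target_draws:
            assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
            for c in m.components:
                np.linalg.cholesky(c.covariance)  # SPD or raises

    def test_convolved_draw_likelihood_matches_direct_fit(self):
        """Average log-likelihood of convolve(target draw, noise draw) on the
        total-signal data sits within sampling error of a direct finite fit
        with matching component count."""
        ds = demo_dataset(n=2000, seed=25)
        cfg = ChainConfig(n_components=2, n_iterations=400, burn_in=200,
                          thin=5, seed=26)
        post = run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 cfg, cfg)
        x = ds.convolved_samples.values
        ll_conv = np.mean([
            m.logpdf(x[:, 0]).mean()
            for m in post.convolved_draws()
        ])
        direct_cfg = ChainConfig(n_components=2, n_iterations=400,
                                 burn_in=200, thin=5, seed=27)
        direct = run_finite_chain(ds.convolved_samples, direct_cfg)
        ll_direct = np.mean([m.logpdf(x[:, 0]).mean() for m in direct])
        assert ll_conv == pytest.approx(ll_direct, abs=0.02)

    def test_dimension_mismatch_rejected(self, rng):
        a = EventTable(rng.normal(size=(50, 1)))
        b = EventTable(rng.normal(size=(50, 2)))
        with pytest.raises(ValueError, match="d="):
            run_deconvolution(a, b)

    def test_posterior_serialization_round_trip(self):
        ds = demo_dataset(n=300, seed=28)
        cfg = ChainConfig(n_components=2, n_iterations=40, burn_in=20,
                          thin=4, seed=29)
        post = run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 cfg, cfg)
        back = DeconvolutionPosterior.from_dict(post.to_dict())
        assert len(back.target_draws) == len(post.target_draws)
        assert np.array_equal(back.target_draws[0].means,
                              post.target_draws[0].means)

    def test_credible_band_orders_around_mean(self):
        ds = demo_dataset(n=600, seed=30)
        cfg = ChainConfig(n_components=3, n_iterations=100, burn_in=50,
                          thin=5, seed=31)
        post = run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 cfg, cfg)
        xs = np.linspace(-3, 4, 101)[:, None]
        lo, hi = post.credible_band(xs)
        mean = post.target_mean_density(xs)
        assert np.all(lo <= hi)
        assert np.all(lo <= mean + 1e-12) and np.all(mean <= hi + 1e-9)

    def test_infinite_target_variant_smoke(self):
        ds = demo_dataset(n=400, seed=32)
        cfg = ChainConfig(n_components=4, n_iterations=80, burn_in=40,
                          thin=4, seed=33)
        post = run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 cfg, cfg, target_model="infinite")
        assert len(post.target_draws) >= 5
        score = posterior_mio(ds.target_truth, post.target_draws,
                              summary="average_density")
        assert score > 0.6


class TestTargetPrior:
    def test_moment_difference_location(self, rng):
        conv = EventTable(rng.normal(2.0, 2.0, size=(5000, 1)))
        noise = EventTable(rng.normal(0.5, 1.0, size=(5000, 1)))
        prior = default_target_prior(conv, noise)
        assert prior.mu0[0] == pytest.approx(1.5, abs=0.1)
        assert prior.sigma0[0, 0] == pytest.approx(3.0, rel=0.15)

    def test_covariance_floor_when_noise_dominates(self, rng):
        conv = EventTable(rng.normal(0.0, 1.0, size=(2000, 1)))
        noise = EventTable(rng.normal(0.0, 2.0, size=(2000, 1)))
        prior = default_target_prior(conv, noise)
        assert prior.sigma0[0, 0] >= 0.09 * np.var(conv.values)
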