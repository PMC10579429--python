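# Methods

## Measurement model and posterior decomposition

The observed total signal per cell is C = T + ξ with target T and
autofluorescence ξ independent, so p_C = p_T ∗ p_ξ.  Both densities are
normal mixtures; the convolution of two normal mixtures is a normal mixture
whose components combine pairwise (weights multiply, means and covariances
add), which keeps the likelihood of the convolved data analytic.

The joint posterior over noise and target mixture parameters factorizes
approximately as

    p(φ_T, φ_ξ | {c}, {ξ}) ≈ p(φ_T | φ_ξ, {c}) · p(φ_ξ | {ξ}),

i.e. the noise posterior is taken to be determined by the noise table alone.
This is accurate when the unlabeled-cell table is comparable in size to the
labeled-cell table, which is the normal cytometry situation.  Stage one fits
the noise mixture; stage two samples the target mixture conditional on a
stored noise draw, cycled through the stored noise posterior (uniform
resampling behind a flag) so noise uncertainty propagates into the target
posterior.

## Conjugate structure

Each mixture component carries a normal-inverse-Wishart prior:
μ | Σ ~ N(μ₀, Σ/κ₀), Σ ~ W⁻¹(Σ₀, ν₀).  With n assigned cells, mean x̄ and
scatter S² (1/n-normalized), the conditionals used by the samplers are

* mean | Σ:  N((n x̄ + κ₀ μ₀)/(n + κ₀), Σ/(n + κ₀));
* Σ | μ:  W⁻¹(n S² + n(x̄−μ)(x̄−μ)ᵀ + κ₀(μ−μ₀)(μ−μ₀)ᵀ + Σ₀, n + ν₀ + 1);
* Σ marginal:  W⁻¹(n S² + (κ₀n/(κ₀+n))(x̄−μ₀)(x̄−μ₀)ᵀ + Σ₀, n + ν₀ + 1);
* posterior predictive: multivariate t with n + ν₀ + 1 − p degrees of
  freedom (the collapsed density used for Dirichlet-process reseating).

Sufficient statistics (n, x̄, S²) are updated in O(d²) when a single cell is
added or removed, so a full Dirichlet-process sweep costs O(N·K) predictive
evaluations.  Inverse-Wishart draws are delegated to scipy
(Bartlett-decomposition sampler), seeded through a single generator per
chain, so every chain is bit-reproducible from its seed.

## Samplers

**Finite mixture.**  Initialization assigns cells by seeded k-means (random
assignment by flag), sets each component to its empirical moments, then
iterates: (1) per-cell indicator draws with weights ω_j N(x_i | μ_j, Σ_j),
computed in log space with log-sum-exp (cells whose weights all underflow
fall back to the max-log-weight component with a warning); (2) weights ~
Dirichlet(n_j + α/K); (3) per component, covariance (conditional on the
current mean), then mean given the new covariance.  Empty components draw
from their prior-only conditionals rather than being deleted, so an
over-specified K is harmless.  Defaults: 2000 iterations, burn-in 1000,
thinning 10, K = 4.

**Dirichlet process.**  Cells are reseated one at a time: the cell is
removed from its component's statistics (a component left empty is
deleted), occupied components attract with weight n_k/(n+α−1) times their
collapsed Student-t predictive, and a new component opens with weight
α/(n+α−1) times the prior predictive (a moment-matched normal flavor is
available behind a flag; the t is the default because its heavier tails
make births less location-sensitive).  After each sweep, weights are drawn
from Dirichlet(n_j + α) and per-component parameters from the
marginal-covariance-then-mean conditionals.  The chain starts from a single
cluster holding all cells: one-site reseating opens components easily but
merges co-located components only through rare moves, so a partitioned
start (e.g. k-means slices of a unimodal cloud) can persist for many
sweeps.

A property worth knowing when reading Dirichlet-process output: the
posterior over the *number* of components does not concentrate — transient
low-weight satellite components carry real posterior mass (the entropy of
the many ways to split a cluster compensates their individually lower
probability).  Density-level summaries are unaffected; component counts
should be read as "number of weight-bearing components" (weight ≥ 0.05 is
the convention used in the tests and examples).

**Convolved sampler (the deconvolution).**  Each labeled cell carries a
latent pair (noise component j, target component k) drawn with probability
∝ ω_j^ξ ω_k^T N(c_i | μ_j^ξ + μ_k^T, Σ_j^ξ + Σ_k^T).  Target weights use the
pair counts summed over j.  The target covariance conditional is not
conjugate: the per-pair inverse-Wishart scale

    Σ̃_jk = n_jk S²_jk + n_jk(x̄_jk − μ_j^ξ − μ_k^T)(·)ᵀ
           + κ₀(μ_k^T − μ₀)(·)ᵀ + Σ₀

is transferred onto the target covariance through the linearization
(Σ_j^ξ + Σ_k^T)⁻¹ ≈ (I − τ̂_jk Σ_j^ξ) (Σ_k^T)⁻¹, where τ̂_jk is the inverse
of the *expected* pair covariance

    Σ̂_jk = (n_jk S²_jk + κ₀(x̄_jk − μ₀)(x̄_jk − μ₀)ᵀ + Σ₀) / (n_jk + ν₀ − p),

the posterior mean of the pair's conditional inverse-Wishart.  The
normalization matters: an un-normalized sum-of-squares in place of Σ̂ would
scale with n, drive the correction factor to the identity, and leave the
variance un-deconvolved.  The corrected scales are aggregated over j,
symmetrized, and the target covariance drawn from
W⁻¹(Σ_j Σ̃_jk (I − τ̂_jk Σ_j^ξ), n_k + ν₀ + 1); the mean then follows from a
multivariate normal with precision Σ_j (n_jk + κ₀)(Σ_j^ξ + Σ_k^T)⁻¹.

Two numerical guards operate in the regime where the noise covariance is
comparable to the pair covariance (low SNR), where the linearization is not
characterized: (1) a correction factor pushed off the SPD cone is projected
back (eigenvalue floor 1e-8 of its trace); (2) the aggregated scale is kept
≥ Σ₀ in the Löwner order — in the noise-free conditional the prior scale
enters additively and unshrunk, and without this floor a clipped-to-zero
correction lets components collapse into point masses.  Both events are
counted in the `spd_clips` chain diagnostic; frequent clipping signals that
the approximation is being stretched.  As the noise covariance vanishes
every correction tends to the identity and the sampler reduces exactly to
the plain finite mixture (verified to MIO ≥ 0.98 in the tests).

The κ₀/μ₀/Σ₀ terms inside the per-pair sum are counted once per noise
component (the prior recurs in each pair term); `normalize_prior=True`
divides them by K_ξ so the prior is counted once overall.  The per-pair
form is the default; on the benchmark the two choices are statistically
indistinguishable at n ≥ 1000 and neither dominates at n = 100.

A Dirichlet-process variant of the target stage (CRP reseating over
(noise, target) pairs with the convolved likelihood, prior-predictive birth
weight on the noise-residual) is provided as an extension
(`target_model="infinite"`); the finite variant is the benchmarked path.

## Hyperparameters

Five hyperparameters, with data-driven defaults chosen where the posterior
is insensitive to them at cytometry sample sizes:

| parameter | meaning | default |
|---|---|---|
| μ₀ | prior component location | dataset mean (noise fit); mean(conv) − mean(noise) (target) |
| Σ₀ | prior component scale | dataset covariance (noise); cov(conv) − cov(noise), eigenvalue-floored at 10% of cov(conv) (target) |
| κ₀ | confidence in μ₀ | 1 |
| ν₀ | confidence in Σ₀ | d + 2 (smallest integer with a finite prior mean of Σ) |
| α | Dirichlet / DP concentration | 1 |

For fat-tailed data the moment-based Σ₀ is inflated by outliers and a
narrower override can sharpen the fit; the estimators accept explicit
`NIWHyperparams` everywhere.

## Synthetic benchmark

The generator crosses three target families × three noise families × two
signal-to-noise ratios × three sample sizes (100 / 1000 / 10000) = 54
datasets.  SNR is defined as Var(target)/Var(noise) on the realized
samples; the noise draws are rescaled so the realized ratio is exact, and
the convolved table is exactly target + scaled noise, row by row.  Frozen
family parameters:

* symmetric bimodal: 0.5 N(−1, 0.5²) + 0.5 N(1, 0.5²);
* asymmetric bimodal: 0.8 N(−0.43, 0.6²) + 0.2 N(1.67, 0.6²) (the worked
  example's target);
* skew symmetric: skew-normal, shape 4;
* noises: N(0,1); skew-normal (shape 4) and Student's t (df 3), both
  centered and standardized before SNR scaling (the latter two fat-tailed).

These constants were chosen once for the qualitative features the benchmark
probes — multiple peaks, unequal cluster sizes, skewness, fat tails — and
are frozen so all reported numbers are reproducible.  What the benchmark
emulates is the additive-noise structure of cytometry data with known
ground truth; what it does not emulate are instrument artifacts
(saturation, spillover, gating truncation) or target–noise dependence, so
passing benchmarks demonstrate correct inference under the additive model,
not robustness to violations of it.  The hardest cell (symmetric bimodal
target under SNR = 1 fat-tailed noise at n = 100) sits near the
identifiability limit: the noise standard deviation exceeds the mode
separation, and the worst-case overlap fluctuates around 0.63–0.75 across
data draws at the reduced MCMC budget used in `scripts/acceptance.py`.

## Metrics

MIO and MISE are computed by trapezoid quadrature on a 4096-point grid
(1-D) or a 512² product grid (2-D) over the union of the supports (mean ±
8 sd per component for mixtures; 1e-9 quantile range for analytic
densities); a window missing more than 1e-3 of either mass raises.  For
d ≥ 3 both integrals switch to self-normalized Monte Carlo with draws from
the equal mixture of the two densities (10⁶ by default).  Posterior draws
are scored either per draw (reported mean ± sd) or through the averaged
density; the averaged density is the deconvolution's headline summary
because it is invariant to label switching, which is deliberately not
corrected.

## Problem sizes used in the shipped runs

The test suite and the acceptance script run the benchmark restricted to
n ∈ {100, 1000} with 1000 iterations / 500 burn-in / thinning 5 and K = 4
for both mixtures; the worked example uses n = 10⁴ with the same budget.
These sizes give stable density summaries (per-draw MIO spread ≲ 0.01 at
n = 10⁴) while keeping a full run in minutes on one CPU; production
analyses of large cytometry tables should raise the iteration budget and
check the `spd_clips` diagnostic before trusting low-SNR fits.

## Known limitations

* The convolved-covariance linearization degrades when the noise covariance
  rivals the per-pair covariance (SNR ≲ 1 with few cells); the Σ₀ floor
  prevents degeneracy but accuracy is then prior-sensitive.
* Individual mixture components are not identifiable (the convolution is
  invariant to shifts between target and noise components that preserve
  summed means and covariances, and labels switch across draws); only
  density-level summaries are supported outputs.
* The Dirichlet-process component count is not a consistent estimate of the
  number of populations; read weight-bearing components instead.
* The spillover model is linear; spectral unmixing beyond a linear mixing
  matrix, and per-event autofluorescence modeling, are out of scope (the
  deconvolution itself replaces the latter).
* FCS support covers list-mode floating-point data (the common case for
  exported, pre-gated tables); integer-mode and multi-dataset files are not
  parsed.
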