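"""Deconvolve a bimodal target from normally distributed autofluorescence.

Builds the worked example: target 0.8 N(-0.43, 0.6^2) + 0.2 N(1.67, 0.6^2),
noise N(0, 0.5^2), 10000 cells each.  Fits the noise, runs the convolved
Gibbs sampler, and scores the deconvolved density against the known target
and against the null model that fits the convolved data directly.
"""
import numpy as np

import scdeconv as sd
from scdeconv.metrics import posterior_mio
from scdeconv.synthetic import demo_dataset

ds = demo_dataset(n=10000, seed=0)
config = sd.ChainConfig(n_components=4, n_iterations=1000, burn_in=500,
                        thin=5, seed=0)

posterior = sd.run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 config, config)
deconv_mio = posterior_mio(ds.target_truth, posterior.target_draws,
                           summary="average_density")
mean_mio, sd_mio = posterior_mio(ds.target_truth, posterior.target_draws)

null_draws = sd.run_finite_chain(ds.convolved_samples, config)
null_mio = posterior_mio(ds.target_truth, null_draws,
                         summary="average_density")

print(f"deconvolved vs true target   MIO = {deconv_mio:.3f} "
      f"(per-draw {mean_mio:.2f} +/- {sd_mio:.2f})")
print(f"null model  vs true target   MIO = {null_mio:.3f}")
print(f"SPD projections during sampling: {posterior.diagnostics['spd_clips']}")

# posterior mean density and 90% band on a grid around the target support
xs = np.linspace(-3.0, 4.0, 9)[:, None]
mean = posterior.target_mean_density(xs)
lo, hi = posterior.credible_band(xs)
print("\n  x      truth   mean   5%     95%")
for x, t, m, a, b in zip(xs[:, 0], ds.target_truth.pdf(xs[:, 0]), mean, lo, hi):
    print(f"{x:5.1f}   {t:.3f}  {m:.3f}  {a:.3f}  {b:.3f}")
print("\nMIO near 1 means the deconvolved density overlaps the truth almost"
      "\ncompletely; the null model stays lower because it reports the"
      "\nnoise-broadened distribution instead of the target.")
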