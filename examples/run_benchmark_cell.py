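"""Score the deconvolution on one cell of the synthetic benchmark.

Picks a deliberately hard configuration -- symmetric bimodal target,
fat-tailed Student's t noise, SNR = 1 -- generates the dataset, deconvolves,
and reports the mean integrated overlap against the known target.
"""
import scdeconv as sd
from scdeconv.metrics import posterior_mio

spec = sd.BenchmarkSpec(
    target_family="symmetric_bimodal",
    noise_family="student_t",
    snr=1.0,
    n=1000,
    seed=0,
)
ds = sd.make_dataset(spec)
print(f"dataset: {spec.label} (noise scale factor {ds.noise_scale:.3f})")

config = sd.ChainConfig(n_components=4, n_iterations=1000, burn_in=500,
                        thin=5, seed=0)
posterior = sd.run_deconvolution(ds.noise_samples, ds.convolved_samples,
                                 config, config)

score = posterior_mio(ds.target_truth, posterior.target_draws,
                      summary="average_density")
noise_score = posterior_mio(ds.noise_truth, posterior.noise_draws,
                            summary="average_density")
print(f"noise fit   MIO = {noise_score:.3f} (4 normal components vs t3 truth)")
print(f"deconvolved MIO = {score:.3f}")
print("\nSNR=1 means the noise variance equals the target variance; an MIO"
      "\naround 0.8-0.9 here shows the two modes survive deconvolution even"
      "\nwhen the noise is as strong as the signal and fat-tailed.")
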