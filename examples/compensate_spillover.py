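"""Estimate a spillover matrix from controls and compensate multichannel data.

Simulates two single-fluorophore controls with known spillover, estimates
the matrix by robust regression, augments it with an autofluorescence
pseudo-fluorophore estimated from noise-only events, and applies the inverse
to recover the fluorophore signals.
"""
import numpy as np

import scdeconv as sd

rng = np.random.default_rng(0)
S_TRUE = np.array([[1.0, 0.08],   # fluorophore A spills 8% into channel B
                   [0.15, 1.0]])  # fluorophore B spills 15% into channel A

controls = {}
for j, name in enumerate(["A", "B"]):
    t = rng.uniform(100, 1000, size=10000)
    vals = np.column_stack([t * S_TRUE[j, 0], t * S_TRUE[j, 1]])
    vals[:, 1 - j] += rng.normal(0, 3.0, size=10000)  # measurement noise
    controls[name] = sd.EventTable(vals, ["A", "B"])

spill = sd.estimate_spillover(controls, {"A": "A", "B": "B"})
print("estimated spillover matrix:")
print(spill.to_frame().round(4))
print(f"max error vs truth: {np.abs(spill.matrix - S_TRUE).max():.2e}")

# autofluorescence as an extra pseudo-fluorophore, from noise-only events
af = rng.normal(120, 25, size=5000)
noise_events = sd.EventTable(
    np.column_stack([0.4 * af + rng.normal(0, 5, 5000),
                     0.2 * af + rng.normal(0, 5, 5000),
                     af]),
    ["A", "B", "AF"],
)
reg = sd.add_autofluorescence_channel(noise_events, "AF")
for ch in ("A", "B"):
    print(f"channel {ch}: noise variance {reg.variance_before[ch]:8.1f} -> "
          f"{reg.variance_after[ch]:6.1f} after regression "
          f"(r = {reg.correlations[ch]:.2f})")

signal = rng.uniform(0, 200, size=(5, 2))
observed = sd.EventTable(signal @ S_TRUE, ["A", "B"])
recovered = sd.apply_compensation(observed, spill)
print("\ntrue signals:     ", np.round(signal[0], 2))
print("after compensation:", np.round(recovered.values[0], 2))
print("\nThe regression shrinks the per-channel noise variance wherever the"
      "\npseudo-channel correlates with the background; the residual noise"
      "\nthat remains is what the deconvolution stage removes.")
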