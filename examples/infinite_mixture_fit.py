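"""Fit a Dirichlet-process mixture when the component count is unknown.

Draws 2000 cells from a two-mode density and lets the infinite sampler
choose how many components to use; prints the distribution of the number of
weight-bearing components across posterior draws and the density overlap
with the truth.
"""
from collections import Counter

import scdeconv as sd
from scdeconv.metrics import posterior_mio
from scdeconv.synthetic import demo_target

truth = demo_target()
data = truth.sample(2000, seed=0)

config = sd.ChainConfig(n_iterations=200, burn_in=100, thin=2, seed=0)
draws = sd.run_infinite_chain(data, config)

substantial = Counter(
    sum(1 for c in m.components if c.weight >= 0.05) for m in draws
)
active = Counter(m.n_components for m in draws)
score = posterior_mio(truth, draws, summary="average_density")

print(f"posterior draws: {len(draws)}")
print(f"active components per draw:      {dict(sorted(active.items()))}")
print(f"substantial (w >= 0.05) per draw: {dict(sorted(substantial.items()))}")
print(f"density overlap with truth: MIO = {score:.3f}")
print("\nThe truth has two modes: a couple of weight-bearing components"
      "\ncarry nearly all the mass while the raw active count runs higher --"
      "\nthe Dirichlet process keeps transient low-weight satellites, which"
      "\nis expected and does not hurt the density estimate.")
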