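"""Compare two densities with the MIO and MISE similarity measures.

Evaluates the closed-form case MIO(N(0,1), N(1,1)) = 2 Phi(-1/2) and shows
how overlap degrades as two normals separate.
"""
import numpy as np
from scipy.stats import norm

import scdeconv as sd

std = sd.MixtureModel([sd.GaussianComponent(1.0, [0.0], [[1.0]])])

print(" shift   MIO      MISE     closed-form MIO")
for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
    other = sd.MixtureModel([sd.GaussianComponent(1.0, [delta], [[1.0]])])
    closed = 2 * norm.cdf(-delta / 2)
    print(f"{delta:6.1f}  {sd.mio(std, other):.4f}  {sd.mise(std, other):.4f}"
          f"   {closed:.4f}")

print("\nMIO is the shared probability mass (1 = identical, 0 = disjoint);"
      "\nfor equal-variance normals it equals 2 Phi(-shift/2), which the"
      "\nquadrature reproduces to four decimals.  MISE is the integrated"
      "\nsquared difference: unbounded above and harder to interpret.")
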