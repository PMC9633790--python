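"""Inspect one fitted phase portrait: spliced mean, unspliced mean, velocity.

Evaluates the closed-form model for a single fitted gene along latent
time and prints the trajectory, showing how velocity changes sign at
the expression peak.
"""

import numpy as np

from rbfvelo import FitConfig, SimSpec, fit, simulate_dataset
from rbfvelo.model import spliced_mean, unspliced_mean, velocity
from rbfvelo.preprocess import prepare

adata = simulate_dataset(SimSpec(n_cells=200, n_genes=60, noise_sd=0.08, seed=3))
prepare(adata, n_neighbors=15)
res = fit(adata, FitConfig(max_iters=1500, seed=3))

# pick the best-explained transient gene (peak inside the window)
transient = np.flatnonzero(res.gene_class == "transient")
j = transient[np.argmax(res.gene_r2[transient])]
p = res.params.subset([j])
print(f"gene {res.gene_names[j]}: tau={p.tau[0]:.2f}, h={p.h[0]:.2f}, "
      f"gamma/beta={p.gamma[0]/p.beta[0]:.2f}, R^2={res.gene_r2[j]:.2f}")

print(f"{'t':>5} {'spliced':>9} {'unspliced':>10} {'velocity':>9}")
for t in np.linspace(0, 1, 11):
    s = spliced_mean(p, t)[0]
    u = unspliced_mean(p, t)[0]
    v = velocity(p, t)[0]
    print(f"{t:5.1f} {s:9.3f} {u:10.3f} {v:9.3f}")
# velocity is positive while t < tau (induction side of the peak),
# zero at the peak, and negative afterwards (repression side).
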