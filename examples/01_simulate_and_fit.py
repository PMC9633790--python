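"""Simulate a differentiation time course and recover it with a unified-time fit.

Builds a 300-cell x 100-gene dataset from the generative RBF model,
runs preprocessing and the unified-mode fit, and compares the inferred
per-cell latent time with the simulation's true time.
"""

import numpy as np
from scipy.stats import spearmanr

from rbfvelo import FitConfig, SimSpec, fit, simulate_dataset
from rbfvelo.preprocess import prepare

adata = simulate_dataset(SimSpec(n_cells=300, n_genes=100, noise_sd=0.1, seed=0))
prepare(adata)
print(f"velocity genes selected: {int(adata.var['velocity_genes'].sum())} / {adata.n_vars}")

res = fit(adata, FitConfig(max_iters=2000, seed=0))
rho = spearmanr(res.time.t, adata.obs["true_time"]).statistic
print(f"final loss: {res.loss_trace[-1]:.1f} after {len(res.loss_trace)} iterations")
print(f"Spearman(inferred latent time, true time) = {rho:.3f}")
# rho near +1 means the shared per-cell ordering matches the simulated
# differentiation axis, including its direction.

mask = adata.var_names.isin(res.gene_names)
acc = np.mean(res.gene_class == adata.var["true_class"].to_numpy()[mask])
print(f"gene-class accuracy (repressed/induction/transient by peak time): {acc:.2%}")
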