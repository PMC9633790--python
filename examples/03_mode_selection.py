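"""Choose between unified-time and independent mode for a dataset.

The heuristic recommends independent mode when cell-cycle marker genes
are enriched among the highly variable genes, or when several clusters
are isolated from the rest of the manifold.  Simulated differentiation
data triggers neither, so the default unified mode is kept.
"""

from rbfvelo import SimSpec, simulate_dataset
from rbfvelo.modes import choose_mode, load_cycle_genes
from rbfvelo.preprocess import prepare

adata = simulate_dataset(SimSpec(n_cells=300, n_genes=80, noise_sd=0.1, seed=4))
prepare(adata, n_neighbors=15)

s_genes, g2m_genes = load_cycle_genes()
print(f"cycle marker lists: {len(s_genes)} S-phase, {len(g2m_genes)} G2M-phase symbols")

rec = choose_mode(adata)
print(rec.to_json())
# mode == "unified": no cycle markers among the simulated gene symbols
# and the time-binned clusters overlap heavily, so no sparsity trigger.
print(f"recommended mode: {rec.mode}")
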