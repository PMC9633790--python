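import numpy as np
import pytest

from rbfvelo import SimSpec, simulate_dataset
from rbfvelo.model import GeneParams
from rbfvelo.preprocess import prepare


def random_gene_params(rng, g=1, offsets=True):
    """Random but well-scaled phase portraits for property tests."""
    return GeneParams(
        h=rng.uniform(0.5, 4.0, g),
        a=rng.uniform(0.5, 6.0, g),
        tau=rng.uniform(-0.5, 1.5, g),
        gamma=rng.uniform(0.3, 2.5, g),
        beta=rng.uniform(0.5, 5.0, g),
        b=rng.uniform(0.5, 3.0, g),
        o=rng.uniform(0.0, 0.5, g) if offsets else np.zeros(g),
        i=rng.uniform(0.0, 0.5, g) if offsets else np.zeros(g),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulation used across modules (read-only)."""
    return simulate_dataset(SimSpec(n_cells=120, n_genes=40, noise_sd=0.1, n_clusters=3, seed=7))


@pytest.fixture(scope="session")
def prepared_sim():
    """A prepared (normalized, smoothed, gene-selected) simulation."""
    adata = simulate_dataset(SimSpec(n_cells=150, n_genes=60, noise_sd=0.08, n_clusters=3, seed=11))
    return prepare(adata, n_neighbors=10)
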