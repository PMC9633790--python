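"""Heuristic choice between unified-time and independent mode.

Unified (gene-shared) time is the default and works well when most
genes move monotonically along one trajectory.  Two dataset features
break that assumption and favour per-gene (independent) time:

* cell-cycle structure — flagged when many S-phase or G2M-phase marker
  genes land among the highly variable genes;
* sparse, disconnected cell types — flagged when several clusters are
  so isolated that nearly all of their cells' KNN neighbors stay
  within the cluster.

The shipped S/G2M marker lists are the widely used curated human
cell-cycle symbol sets (one symbol per line, user-replaceable files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from anndata import AnnData

log = logging.getLogger(__name__)

__all__ = [
    "ModeRecommendation",
    "load_cycle_genes",
    "count_cycle_hvgs",
    "detect_sparse_clusters",
    "choose_mode",
]


@dataclass
class ModeRecommendation:
    """Recommended mode plus the evidence that produced it."""

    mode: str
    n_cycle_hvgs_S: int
    n_cycle_hvgs_G2M: int
    sparse_clusters: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=str, indent=2)


def load_cycle_genes(s_file=None, g2m_file=None):
    """Load S and G2M marker symbol lists (defaults ship with the package)."""

    def _read(path, default_name):
        if path is not None:
            with open(path) as fh:
                return [ln.strip() for ln in fh if ln.strip()]
        text = resources.files("rbfvelo.data").joinpath(default_name).read_text()
        return [ln.strip() for ln in text.splitlines() if ln.strip()]

    return _read(s_file, "s_genes.txt"), _read(g2m_file, "g2m_genes.txt")


def count_cycle_hvgs(adata: AnnData, s_genes, g2m_genes):
    """Count S/G2M marker genes among the highly variable genes.

    Matching is case-insensitive on gene symbols.  Empty marker lists
    are an error — the heuristic cannot be assessed without them.
    """
    if not s_genes or not g2m_genes:
        raise ValueError("cycle gene lists must be non-empty")
    hvg = adata.var.get("highly_variable")
    hvg = np.ones(adata.n_vars, bool) if hvg is None else hvg.to_numpy()
    symbols = {s.upper() for s in adata.var_names[hvg]}
    n_s = sum(1 for g in s_genes if g.upper() in symbols)
    n_g2m = sum(1 for g in g2m_genes if g.upper() in symbols)
    return n_s, n_g2m


def detect_sparse_clusters(
    adata: AnnData, purity: float = 0.95, cluster_key: str = "clusters"
) -> list:
    """Find clusters whose cells' neighborhoods are almost purely internal.

    A cluster is sparse when the mean, over its cells, of the fraction
    of KNN neighbors sharing the cell's label exceeds ``purity``.
    """
    clusters = np.asarray(adata.obs[cluster_key]).astype(str)
    labels = np.unique(clusters)
    if labels.size < 2:
        return []
    knn = np.asarray(adata.obsm["knn_indices"])
    sparse_labels = []
    for lab in labels:
        cells = np.flatnonzero(clusters == lab)
        fracs = []
        for c in cells:
            nbrs = knn[c]
            nbrs = nbrs[nbrs != c]
            if nbrs.size:
                fracs.append(np.mean(clusters[nbrs] == lab))
        if fracs and np.mean(fracs) > purity:
            sparse_labels.append(lab)
    return sparse_labels


def choose_mode(
    adata: AnnData,
    s_genes=None,
    g2m_genes=None,
    cycle_frac: float = 0.5,
    n_clusters_min: int = 2,
    purity: float = 0.95,
    cluster_key: str = "clusters",
) -> ModeRecommendation:
    """Recommend unified vs independent mode.

    Independent mode is recommended when either trigger fires: the
    count of S (or G2M) markers among HVGs exceeds ``cycle_frac`` of
    the respective list, or strictly more than ``n_clusters_min``
    clusters are sparse at the given ``purity``.  Otherwise the
    default unified mode is kept.  Pure function of its inputs.
    """
    if s_genes is None or g2m_genes is None:
        s_def, g2m_def = load_cycle_genes()
        s_genes = s_def if s_genes is None else s_genes
        g2m_genes = g2m_def if g2m_genes is None else g2m_genes
    n_s, n_g2m = count_cycle_hvgs(adata, s_genes, g2m_genes)
    cycle_trigger = n_s > cycle_frac * len(s_genes) or n_g2m > cycle_frac * len(g2m_genes)

    sparse_labels = detect_sparse_clusters(adata, purity=purity, cluster_key=cluster_key)
    sparse_trigger = len(sparse_labels) > n_clusters_min

    rec = ModeRecommendation(
        mode="independent" if (cycle_trigger or sparse_trigger) else "unified",
        n_cycle_hvgs_S=n_s,
        n_cycle_hvgs_G2M=n_g2m,
        sparse_clusters=list(sparse_labels),
        thresholds={
            "cycle_frac": cycle_frac,
            "n_clusters_min": n_clusters_min,
            "purity": purity,
        },
    )
    log.info("mode recommendation: %s", rec.to_json())
    return rec
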