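"""Goodness-of-fit and trajectory-direction metrics.

Per-gene R^2 measures how much spliced variance the fitted time
function explains.  For directionality, gene-space velocities are first
projected onto the low-dimensional embedding via the standard
transition-probability scheme (cosine similarity between a cell's
velocity and the expression displacement to each neighbor, softmax
weighted); two metrics then summarize the embedded field:

* CBDir (cross-boundary direction correctness): for cells of a source
  cluster lying on the boundary with a ground-truth target cluster,
  the mean cosine between the cell's projected velocity and the
  displacement vectors toward its target-cluster neighbors.
* ICCoh (in-cluster coherence): the mean cosine similarity of a cell's
  velocity with those of its same-cluster neighbors.  Note ICCoh is
  direction-blind — a uniformly reversed field scores identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .model import spliced_mean
from .inference import FitResult

log = logging.getLogger(__name__)

__all__ = ["EvalReport", "gene_r2", "project_velocity", "cbdir", "iccoh", "evaluate_fit"]


@dataclass
class EvalReport:
    """Direction-metric summaries for one fitted model."""

    gene_r2: pd.Series
    cbdir_per_pair: dict
    cbdir_per_cell: pd.Series
    iccoh_per_cluster: dict
    iccoh_per_cell: pd.Series
    transitions: list

    @property
    def cbdir_mean(self) -> float:
        """Unweighted mean over cluster pairs."""
        vals = [v for v in self.cbdir_per_pair.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def cbdir_cell_weighted_mean(self) -> float:
        """Mean over all boundary cells (pairs weighted by boundary size)."""
        return float(self.cbdir_per_cell.mean())

    @property
    def iccoh_mean(self) -> float:
        vals = [v for v in self.iccoh_per_cluster.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [("CBDir", src, dst, val) for (src, dst), val in self.cbdir_per_pair.items()]
        rows += [("ICCoh", c, "", val) for c, val in self.iccoh_per_cluster.items()]
        return pd.DataFrame(rows, columns=["metric", "source", "target", "score"])


def gene_r2(fit: FitResult, adata: AnnData) -> pd.Series:
    """R^2 of the fitted spliced mean at the assigned times, per gene.

    ``1 - MSE/Var`` of the smoothed spliced layer; negative for fits
    worse than predicting the gene mean, NaN for zero-variance genes.
    """
    mask = adata.var_names.isin(fit.gene_names)
    ms = np.asarray(adata.layers["Ms"])[:, mask].astype(float)
    pred = spliced_mean(fit.params, fit.time.t)
    mse = ((ms - pred) ** 2).mean(axis=0)
    var = ms.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var > 0, 1.0 - mse / var, np.nan)
    return pd.Series(r2, index=fit.gene_names, name="gene_r2")


def project_velocity(
    velocity: np.ndarray,
    expression: np.ndarray,
    embedding: np.ndarray,
    knn_indices: np.ndarray,
) -> np.ndarray:
    """Project gene-space velocities into the embedding.

    For each cell the cosine similarity between its velocity vector and
    the expression displacement to every KNN neighbor is turned into
    transition weights by a softmax (temperature 1/mean|cos| per cell),
    and the projected velocity is the weighted mean of the embedding
    displacements.  Cells with zero velocity (or no neighbors) map to
    the zero vector.
    """
    n = velocity.shape[0]
    out = np.zeros((n, embedding.shape[1]))
    vnorm = np.linalg.norm(velocity, axis=1)
    for c in range(n):
        nbrs = knn_indices[c]
        nbrs = nbrs[nbrs != c]
        if nbrs.size == 0 or vnorm[c] == 0:
            if nbrs.size == 0:
                log.warning("cell %d has no neighbors; zero projected velocity", c)
            continue
        delta = expression[nbrs] - expression[c]
        dnorm = np.linalg.norm(delta, axis=1)
        ok = dnorm > 0
        cos = np.zeros(nbrs.size)
        cos[ok] = delta[ok] @ velocity[c] / (dnorm[ok] * vnorm[c])
        scale = np.mean(np.abs(cos)) + 1e-12
        w = np.exp((cos - cos.max()) / (1.0 / scale))
        w /= w.sum()
        out[c] = w @ (embedding[nbrs] - embedding[c])
    return out


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(u @ v / (nu * nv))


def cbdir(
    v_low: np.ndarray,
    x_low: np.ndarray,
    clusters,
    transitions,
    knn_indices: np.ndarray,
):
    """Cross-boundary direction correctness per ground-truth transition.

    For every (source, target) pair, boundary cells are source-cluster
    cells with at least one KNN neighbor in the target cluster; each
    scores the mean cosine between its projected velocity and the
    embedding displacements to those neighbors.  Returns
    ``(per_pair, per_cell)``; pairs without boundary cells are reported
    as NaN rather than zero.
    """
    clusters = np.asarray(clusters).astype(str)
    per_pair: dict = {}
    cell_scores: dict = {}
    for src, dst in transitions:
        scores = []
        for c in np.flatnonzero(clusters == str(src)):
            nbrs = knn_indices[c]
            nbrs = nbrs[nbrs != c]
            tgt = nbrs[clusters[nbrs] == str(dst)]
            if tgt.size == 0:
                continue
            cos = [_cosine(v_low[c], x_low[j] - x_low[c]) for j in tgt]
            cos = [x for x in cos if np.isfinite(x)]
            if cos:
                score = float(np.mean(cos))
                scores.append(score)
                cell_scores[c] = score
        per_pair[(str(src), str(dst))] = float(np.mean(scores)) if scores else np.nan
        if not scores:
            log.warning("no boundary cells for transition %s -> %s", src, dst)
    return per_pair, pd.Series(cell_scores, name="cbdir")


def iccoh(v_low: np.ndarray, clusters, knn_indices: np.ndarray):
    """In-cluster velocity coherence per cell and per cluster.

    Mean cosine similarity of each cell's projected velocity with those
    of its same-cluster neighbors; zero-norm velocities are skipped.
    """
    clusters = np.asarray(clusters).astype(str)
    norms = np.linalg.norm(v_low, axis=1)
    per_cell = np.full(v_low.shape[0], np.nan)
    for c in range(v_low.shape[0]):
        if norms[c] == 0:
            continue
        nbrs = knn_indices[c]
        nbrs = nbrs[(nbrs != c) & (clusters[nbrs] == clusters[c]) & (norms[nbrs] > 0)]
        if nbrs.size == 0:
            continue
        per_cell[c] = float(
            np.mean(v_low[nbrs] @ v_low[c] / (norms[nbrs] * norms[c]))
        )
    per_cluster = {
        lab: float(np.nanmean(per_cell[clusters == lab]))
        if np.isfinite(per_cell[clusters == lab]).any()
        else np.nan
        for lab in np.unique(clusters)
    }
    return per_cluster, pd.Series(per_cell, name="iccoh")


def evaluate_fit(
    fit: FitResult,
    adata: AnnData,
    transitions,
    cluster_key: str = "clusters",
    embedding_key: str | None = None,
) -> EvalReport:
    """Full evaluation: R^2, velocity projection, CBDir and ICCoh."""
    if embedding_key is None:
        embedding_key = "X_umap" if "X_umap" in adata.obsm else "X_pca"
    emb = np.asarray(adata.obsm[embedding_key])[:, :2]
    knn = np.asarray(adata.obsm["knn_indices"])
    mask = adata.var_names.isin(fit.gene_names)
    ms = np.asarray(adata.layers["Ms"])[:, mask].astype(float)

    v_low = project_velocity(fit.velocity_matrix, ms, emb, knn)
    clusters = adata.obs[cluster_key].to_numpy()
    pair, cell = cbdir(v_low, emb, clusters, transitions, knn)
    clus, icc_cell = iccoh(v_low, clusters, knn)
    return EvalReport(
        gene_r2=gene_r2(fit, adata),
        cbdir_per_pair=pair,
        cbdir_per_cell=cell,
        iccoh_per_cluster=clus,
        iccoh_per_cell=icc_cell,
        transitions=list(transitions),
    )
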