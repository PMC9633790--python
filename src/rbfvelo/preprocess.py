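"""Dataset preparation: filtering, normalization, smoothing, gene selection.

Operates in place on an AnnData with ``spliced`` / ``unspliced`` layers.
The prepared object carries size-normalized layers, KNN-smoothed first
moments (``Ms`` / ``Mu``), a highly-variable-gene mask and the final
``velocity_genes`` mask used for model fitting.
"""

from __future__ import annotations

import logging

import numpy as np
import scanpy as sc
from anndata import AnnData
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

__all__ = [
    "normalize_and_filter",
    "select_hvg",
    "knn_moments",
    "select_velocity_genes",
    "amplify_velocity_genes",
    "prepare",
]


def _dense(layer) -> np.ndarray:
    return np.asarray(layer.todense()) if sparse.issparse(layer) else np.asarray(layer, dtype=float)


def normalize_and_filter(adata: AnnData, min_cells: int = 20) -> AnnData:
    """Drop weakly covered genes and size-normalize both layers.

    A gene is kept only if at least ``min_cells`` cells have nonzero
    counts in *both* the spliced and unspliced layer.  Each layer is
    then normalized per cell so that every cell's total matches the
    median total of that layer (spliced and unspliced are scaled by
    their own size factors, preserving within-cell proportions).
    """
    for key in ("spliced", "unspliced"):
        if key not in adata.layers:
            raise KeyError(f"missing required layer '{key}'")
    s = _dense(adata.layers["spliced"])
    u = _dense(adata.layers["unspliced"])

    expressed = ((s > 0) & (u > 0)).sum(axis=0)
    keep = expressed >= min_cells
    if not keep.any():
        raise ValueError(
            f"no gene is expressed (spliced and unspliced) in >= {min_cells} cells"
        )
    adata._inplace_subset_var(np.asarray(keep).ravel())
    s, u = s[:, keep], u[:, keep]

    for name, layer in (("spliced", s), ("unspliced", u)):
        totals = layer.sum(axis=1)
        totals[totals == 0] = 1.0
        factors = totals / np.median(totals[totals > 0])
        adata.layers[name + "_norm"] = layer / factors[:, None]
    adata.X = adata.layers["spliced_norm"].copy()
    return adata


def select_hvg(adata: AnnData, n_top: int = 2000) -> np.ndarray:
    """Mark highly variable genes by mean-binned normalized dispersion."""
    if "spliced_norm" not in adata.layers:
        raise KeyError("run normalize_and_filter first ('spliced_norm' missing)")
    if n_top >= adata.n_vars:
        log.warning(
            "n_top=%d >= %d genes available; keeping all genes", n_top, adata.n_vars
        )
        adata.var["highly_variable"] = True
        return adata.var["highly_variable"].to_numpy()
    tmp = AnnData(X=np.log1p(adata.layers["spliced_norm"]))
    sc.pp.highly_variable_genes(tmp, n_top_genes=n_top, flavor="seurat")
    mask = tmp.var["highly_variable"].to_numpy()
    if mask.sum() > n_top:  # degenerate binning can over-select on tiny inputs
        disp = np.nan_to_num(tmp.var["dispersions_norm"].to_numpy(), nan=-np.inf)
        raw = np.nan_to_num(tmp.var["dispersions"].to_numpy(), nan=-np.inf)
        order = np.lexsort((-raw, -disp))  # ties in normalized dispersion -> raw
        mask = np.zeros(adata.n_vars, bool)
        mask[order[:n_top]] = True
    adata.var["highly_variable"] = mask
    return mask


def knn_moments(adata: AnnData, n_pcs: int = 30, n_neighbors: int = 30) -> AnnData:
    """Smooth both layers by averaging over each cell's KNN neighborhood.

    The graph is built with Euclidean distances in PCA space of the
    log1p spliced layer.  The neighborhood includes the cell itself,
    which stabilizes small neighborhoods; with k = 1 smoothing is the
    identity.  Results go to layers ``Ms`` and ``Mu``; neighbor indices
    are stored in ``obsm['knn_indices']``.
    """
    s = np.log1p(_dense(adata.layers["spliced_norm"]))
    n_comps = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    pcs = sc.pp.pca(s, n_comps=n_comps, svd_solver="arpack")
    adata.obsm["X_pca"] = pcs

    k = n_neighbors
    if k > adata.n_obs:
        log.warning("n_neighbors=%d > %d cells; reducing", k, adata.n_obs)
        k = adata.n_obs
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    adata.obsm["knn_indices"] = idx
    adata.uns["neighbors"] = {"n_neighbors": k, "n_pcs": n_comps}

    for src, dst in (("spliced_norm", "Ms"), ("unspliced_norm", "Mu")):
        vals = _dense(adata.layers[src])
        adata.layers[dst] = vals[idx].mean(axis=1)
    return adata


def select_velocity_genes(
    adata: AnnData,
    min_gamma: float = 0.01,
    min_r2: float = 0.01,
    sigma_lo: float = 0.03,
    sigma_hi: float = 3.0,
) -> np.ndarray:
    """Select genes with credible splicing kinetics for model fitting.

    Per highly variable gene, a zero-intercept least-squares fit of the
    smoothed unspliced on the smoothed spliced layer (the steady-state
    slope estimator) must give slope > ``min_gamma`` and R^2 >
    ``min_r2``, and the ratio sd(u)/sd(s) must lie within
    [``sigma_lo``, ``sigma_hi``].  Zero-variance genes are excluded.
    """
    mu, ms = _dense(adata.layers["Mu"]), _dense(adata.layers["Ms"])
    hvg = adata.var.get("highly_variable")
    hvg = np.ones(adata.n_vars, bool) if hvg is None else hvg.to_numpy()

    ss = (ms * ms).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (mu * ms).sum(axis=0) / ss
        resid = mu - slope * ms
        sst = ((mu - mu.mean(axis=0)) ** 2).sum(axis=0)
        r2 = 1.0 - (resid * resid).sum(axis=0) / sst
        ratio = mu.std(axis=0) / ms.std(axis=0)

    ok = np.isfinite(slope) & np.isfinite(r2) & np.isfinite(ratio)
    mask = (
        hvg & ok
        & (slope > min_gamma)
        & (r2 > min_r2)
        & (ratio >= sigma_lo)
        & (ratio <= sigma_hi)
    )
    adata.var["velocity_genes"] = mask
    adata.var["steady_state_gamma"] = np.where(ok, slope, np.nan)
    adata.var["steady_state_r2"] = np.where(ok, r2, np.nan)
    log.info("selected %d / %d velocity genes", int(mask.sum()), adata.n_vars)
    return mask


def amplify_velocity_genes(adata: AnnData, cell_time, r2_threshold: float) -> np.ndarray:
    """Expand the velocity-gene mask using an interim unified cell time.

    For each highly variable gene currently excluded, the smoothed
    spliced profile is regressed (with intercept) on the interim cell
    time; genes whose R^2 exceeds ``r2_threshold`` (the ``AGENES_R2``
    configuration value) are added to ``velocity_genes``.  Requires a
    unified (per-cell scalar) time; in independent mode this is a no-op.
    """
    t = np.asarray(getattr(cell_time, "t", cell_time), dtype=float)
    if t.ndim != 1:
        log.warning("amplify_velocity_genes needs a unified cell time; skipping")
        return adata.var["velocity_genes"].to_numpy()
    mask = adata.var["velocity_genes"].to_numpy().copy()
    hvg = adata.var.get("highly_variable")
    hvg = np.ones(adata.n_vars, bool) if hvg is None else hvg.to_numpy()
    candidates = np.flatnonzero(hvg & ~mask)
    if candidates.size == 0:
        return mask

    ms = _dense(adata.layers["Ms"])[:, candidates]
    tc = t - t.mean()
    denom = (tc * tc).sum()
    yc = ms - ms.mean(axis=0)
    beta = tc @ yc / denom
    sse = (yc * yc).sum(axis=0) - beta**2 * denom
    sst = (yc * yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    added = candidates[r2 > r2_threshold]
    mask[added] = True
    adata.var["velocity_genes"] = mask
    log.info("amplified velocity genes: +%d (threshold %.3g)", added.size, r2_threshold)
    return mask


def prepare(
    adata: AnnData,
    min_cells: int = 20,
    n_top_genes: int = 2000,
    n_pcs: int = 30,
    n_neighbors: int = 30,
    min_gamma: float = 0.01,
    min_r2: float = 0.01,
    sigma_lo: float = 0.03,
    sigma_hi: float = 3.0,
) -> AnnData:
    """Full preprocessing chain, in the standard order."""
    normalize_and_filter(adata, min_cells=min_cells)
    select_hvg(adata, n_top=n_top_genes)
    knn_moments(adata, n_pcs=n_pcs, n_neighbors=n_neighbors)
    select_velocity_genes(
        adata, min_gamma=min_gamma, min_r2=min_r2,
        sigma_lo=sigma_lo, sigma_hi=sigma_hi,
    )
    return adata
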