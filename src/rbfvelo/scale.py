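"""Down-sampling for large datasets and prediction for held-out cells.

The model is fitted on a stratified subset (every cluster keeps at
least a minimum number of cells) and the held-out cells receive latent
times and velocities by the same projection step used during training:
grid search onto the frozen phase trajectories, followed by quantile
mapping of the per-gene times against the training distribution so the
held-out unified times live on the same [0, 1] scale.
"""

from __future__ import annotations

import numpy as np
from anndata import AnnData

from .inference import FitResult, assign_time
from .model import LatentTime, velocity

__all__ = ["stratified_downsample", "predict_heldout"]


def stratified_downsample(
    adata: AnnData,
    frac: float,
    min_per_cluster: int = 50,
    seed: int = 0,
    cluster_key: str = "clusters",
):
    """Split cells into train/held-out indices, stratified by cluster.

    Each cluster contributes ``max(min_per_cluster, frac * size)``
    cells (capped at its size), sampled without replacement; every
    cluster therefore stays represented.  Deterministic under ``seed``.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    clusters = np.asarray(adata.obs[cluster_key]).astype(str)
    train = []
    for lab in np.unique(clusters):
        cells = np.flatnonzero(clusters == lab)
        n_keep = min(cells.size, max(min_per_cluster, int(round(frac * cells.size))))
        train.append(rng.choice(cells, size=n_keep, replace=False))
    train_idx = np.sort(np.concatenate(train))
    heldout_idx = np.setdiff1d(np.arange(adata.n_obs), train_idx)
    return train_idx, heldout_idx


def predict_heldout(fit: FitResult, adata: AnnData, heldout_idx):
    """Predict latent time and velocity for cells not used in fitting.

    Held-out cells are projected onto the fitted trajectories by the
    training grid search; per gene, each held-out time is mapped to its
    quantile within the training assignments (empirical CDF), and the
    quantiles are averaged across genes into a unified time comparable
    with the training scale.  Velocities come from the model derivative
    at the predicted times.  Deterministic given the fit.
    """
    heldout_idx = np.asarray(heldout_idx, dtype=int)
    mask = adata.var_names.isin(fit.gene_names)
    missing = [g for g in fit.gene_names if g not in adata.var_names]
    if missing:
        raise KeyError(f"fitted genes missing from dataset: {missing[:5]}")
    mu = np.asarray(adata.layers["Mu"])[:, mask].astype(float)
    ms = np.asarray(adata.layers["Ms"])[:, mask].astype(float)

    grid_size = fit.config.grid_size
    if heldout_idx.size == 0:
        empty = np.empty((0,))
        return LatentTime("unified", empty), np.empty((0, mask.sum()))

    t_ng = assign_time(fit.params, mu[heldout_idx], ms[heldout_idx], grid_size)

    if fit.time.mode == "independent":
        time = LatentTime("independent", t_ng)
        return time, velocity(fit.params, t_ng)

    # training per-gene assignments define the reference distribution
    train_idx = np.setdiff1d(np.arange(adata.n_obs), heldout_idx)
    t_train = assign_time(fit.params, mu[train_idx], ms[train_idx], grid_size)
    n_train, g = t_train.shape
    q = np.empty_like(t_ng)
    for j in range(g):
        ref = np.sort(t_train[:, j])
        # mid-rank ECDF: fraction of training times at or below each value
        hi = np.searchsorted(ref, t_ng[:, j], side="right")
        lo = np.searchsorted(ref, t_ng[:, j], side="left")
        q[:, j] = (lo + hi) / (2.0 * n_train)
    t_unified = np.clip(q.mean(axis=1), 0.0, 1.0)
    return LatentTime("unified", t_unified), velocity(fit.params, t_unified)
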