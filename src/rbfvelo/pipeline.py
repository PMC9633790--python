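"""End-to-end pipeline: preprocess, choose mode, fit, evaluate, write.

``run_pipeline`` ties the library modules into one reproducible run.
Configuration precedence is CLI flag > config file > built-in default;
the resolved settings, seed and package version are recorded in the
output container as a run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from anndata import AnnData

from .evaluate import EvalReport, evaluate_fit
from .inference import FitConfig, FitResult, fit
from .modes import choose_mode
from .preprocess import amplify_velocity_genes, prepare
from .scale import predict_heldout, stratified_downsample

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with the standard defaults."""

    mode: str = "auto"  # auto | unified | independent
    min_cells: int = 20
    n_top_genes: int = 2000
    n_neighbors: int = 30
    n_pcs: int = 30
    min_gamma: float = 0.01
    min_r2: float = 0.01
    sigma_lo: float = 0.03
    sigma_hi: float = 3.0
    agenes_r2: float | None = None
    conv_tol: float = 1e-4
    max_iters: int = 12000
    reassign_every: int = 10
    grid_size: int = 100
    learning_rate: float = 0.01
    denoise_dims: int = 50
    downsample_frac: float | None = None
    min_per_cluster: int = 50
    cluster_key: str = "clusters"
    seed: int = 0

    def fit_config(self, mode: str) -> FitConfig:
        return FitConfig(
            max_iters=self.max_iters,
            reassign_every=self.reassign_every,
            grid_size=self.grid_size,
            learning_rate=self.learning_rate,
            conv_tol=self.conv_tol,
            mode=mode,
            denoise_dims=self.denoise_dims,
            seed=self.seed,
        )


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    values = {}
    if path is not None:
        with open(path) as fh:
            values.update(yaml.safe_load(fh) or {})
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def run_pipeline(
    adata: AnnData,
    config: PipelineConfig | None = None,
    transitions=None,
):
    """Run preprocessing, mode selection, fitting and evaluation in place.

    Returns ``(adata, fit_result, eval_report)``; the report is None
    when no ground-truth transitions are supplied.  The fitted
    velocity layer, latent time and per-gene annotations are written
    back into ``adata`` together with a run manifest under
    ``uns['rbfvelo']``.
    """
    config = config or PipelineConfig()
    prepare(
        adata,
        min_cells=config.min_cells,
        n_top_genes=config.n_top_genes,
        n_pcs=config.n_pcs,
        n_neighbors=config.n_neighbors,
        min_gamma=config.min_gamma,
        min_r2=config.min_r2,
        sigma_lo=config.sigma_lo,
        sigma_hi=config.sigma_hi,
    )

    mode = config.mode
    recommendation = None
    if mode == "auto":
        recommendation = choose_mode(adata, cluster_key=config.cluster_key)
        mode = recommendation.mode
        log.info("auto mode selection: %s", mode)

    result = fit(adata, config.fit_config(mode))

    if config.agenes_r2 is not None and mode == "unified":
        before = int(adata.var["velocity_genes"].sum())
        mask = amplify_velocity_genes(adata, result.time, config.agenes_r2)
        if int(mask.sum()) > before:
            result = fit(adata, config.fit_config(mode))

    if config.downsample_frac is not None and config.downsample_frac < 1.0:
        import numpy as np

        train_idx, heldout_idx = stratified_downsample(
            adata,
            frac=config.downsample_frac,
            min_per_cluster=config.min_per_cluster,
            seed=config.seed,
            cluster_key=config.cluster_key,
        )
        sub = adata[train_idx].copy()
        sub_result = fit(sub, config.fit_config(mode))
        time, vel = predict_heldout(sub_result, adata, heldout_idx)
        mask = adata.var_names.isin(sub_result.gene_names)
        full_vel = np.zeros((adata.n_obs, adata.n_vars))
        full_vel[np.ix_(train_idx, np.flatnonzero(mask))] = sub_result.velocity_matrix
        full_vel[np.ix_(heldout_idx, np.flatnonzero(mask))] = vel
        full_time = np.empty(adata.n_obs)
        full_time[train_idx] = (
            sub_result.time.t
            if sub_result.time.mode == "unified"
            else sub_result.time.t.mean(axis=1)
        )
        full_time[heldout_idx] = time.t if time.mode == "unified" else time.t.mean(axis=1)
        adata.layers["velocity"] = full_vel
        adata.obs["latent_time"] = full_time
        adata.uns["rbfvelo_heldout"] = {"heldout_idx": heldout_idx, "time": time.t}
        result = sub_result
    else:
        result.write_to(adata)

    report = None
    if transitions is not None:
        if result.velocity_matrix.shape[0] != adata.n_obs:
            log.warning(
                "evaluation after down-sampling uses train cells only"
            )
            from sklearn.neighbors import NearestNeighbors

            sub_eval = adata[train_idx].copy()
            k = int(adata.uns["neighbors"]["n_neighbors"])
            nn = NearestNeighbors(n_neighbors=min(k, sub_eval.n_obs)).fit(
                sub_eval.obsm["X_pca"]
            )
            _, sub_eval.obsm["knn_indices"] = nn.kneighbors(sub_eval.obsm["X_pca"])
            report = evaluate_fit(
                result, sub_eval, transitions, cluster_key=config.cluster_key
            )
        else:
            report = evaluate_fit(
                result, adata, transitions, cluster_key=config.cluster_key
            )
        adata.uns["rbfvelo_eval"] = report.to_frame()

    from importlib.metadata import version as _pkg_version

    try:
        pkg_version = _pkg_version("rbfvelo")
    except Exception:
        pkg_version = "unknown"
    adata.uns["rbfvelo"] = {
        "version": pkg_version,
        "config": {k: ("" if v is None else v) for k, v in asdict(config).items()},
        "mode_used": mode,
        "mode_recommendation": "" if recommendation is None else recommendation.mode,
    }
    return adata, result, report
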