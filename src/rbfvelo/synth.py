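"""Forward simulation of spliced/unspliced profiles from the RBF model.

The generator draws a latent differentiation time per cell, draws one
phase portrait per gene from an induction / repression / transient
class mix, evaluates the model means, and adds zero-truncated Gaussian
noise.  Cells are binned along true time into ordered cluster labels so
that cluster-to-cluster transitions provide a known ground-truth
direction for evaluation.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .model import GeneParams, spliced_mean, unspliced_mean, velocity

__all__ = ["SimSpec", "simulate_dataset"]


@dataclass
class SimSpec:
    """Configuration of one simulated dataset.

    ``noise_sd`` is expressed as a fraction of each gene's amplitude
    ``h`` so that signal-to-noise is comparable across genes; 0.1 gives
    the moderately noisy regime typical of KNN-smoothed single-cell
    layers.  ``frac_*`` set the gene-class mix and must sum to 1.
    A MURK-like regime (a late multiplicative boost of the spliced
    amplitude, violating the constant-rate assumption) can be switched
    on as a stressor via ``frac_murk`` > 0, carved out of the
    induction fraction.
    """

    n_cells: int = 500
    n_genes: int = 200
    frac_induction: float = 0.35
    frac_repression: float = 0.35
    frac_transient: float = 0.30
    noise_sd: float = 0.1
    true_time: str = "uniform"  # or "beta"
    n_clusters: int = 5
    frac_murk: float = 0.0
    seed: int = 0
    beta_params: tuple = field(default=(2.0, 2.0))

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        fr = self.frac_induction + self.frac_repression + self.frac_transient
        if abs(fr - 1.0) > 1e-8:
            raise ValueError("gene-class fractions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.frac_murk <= self.frac_induction:
            raise ValueError("frac_murk must lie in [0, frac_induction]")
        if self.true_time not in ("uniform", "beta"):
            raise ValueError("true_time must be 'uniform' or 'beta'")


def _draw_params(spec: SimSpec, rng: np.random.Generator):
    """Draw per-gene phase portraits by class.

    Peak times land strictly outside [0, 1] for monotone classes
    (induction tau in (1.05, 1.5), repression tau in (-0.5, -0.05))
    and inside (0.3, 0.7) for transient genes, so every gene's class
    is unambiguous under the tau thresholds.
    """
    g = spec.n_genes
    n_ind = int(round(spec.frac_induction * g))
    n_rep = int(round(spec.frac_repression * g))
    n_tra = g - n_ind - n_rep
    classes = np.array(
        ["induction"] * n_ind + ["repressed"] * n_rep + ["transient"] * n_tra
    )
    rng.shuffle(classes)

    tau = np.empty(g)
    tau[classes == "induction"] = rng.uniform(1.05, 1.5, (classes == "induction").sum())
    tau[classes == "repressed"] = rng.uniform(-0.5, -0.05, (classes == "repressed").sum())
    tau[classes == "transient"] = rng.uniform(0.3, 0.7, (classes == "transient").sum())

    # kinetic ranges chosen so unspliced magnitudes are a modest fraction
    # of spliced ones, as in real normalized single-cell layers
    params = GeneParams(
        h=rng.uniform(1.0, 5.0, g),
        a=rng.uniform(1.0, 4.0, g),
        tau=tau,
        gamma=rng.uniform(0.5, 2.0, g),
        beta=rng.uniform(2.0, 6.0, g),
        b=np.ones(g),
        o=np.zeros(g),
        i=np.zeros(g),
    )
    return params, classes


def simulate_dataset(spec: SimSpec) -> AnnData:
    """Simulate one dataset; returns an AnnData with ground truth in ``uns``.

    Layers ``spliced`` / ``unspliced`` hold the noisy observations,
    ``obs['clusters']`` the ordered time-bin labels.  Ground truth is
    stored under ``uns['truth']``: true per-cell time, true parameter
    arrays, true velocity matrix, gene classes, and the ordered
    bin-to-bin transition pairs.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.true_time == "uniform":
        t_true = rng.uniform(0.0, 1.0, spec.n_cells)
    else:
        t_true = rng.beta(*spec.beta_params, spec.n_cells)

    params, classes = _draw_params(spec, rng)

    s_mean = spliced_mean(params, t_true)
    u_mean = unspliced_mean(params, t_true)
    vel_true = velocity(params, t_true)

    if spec.frac_murk > 0:
        n_murk = int(round(spec.frac_murk * spec.n_genes))
        murk_idx = rng.choice(
            np.flatnonzero(classes == "induction"),
            size=min(n_murk, (classes == "induction").sum()),
            replace=False,
        )
        # late transcriptional boost: amplitude ramps up for t > 0.7
        boost = 1.0 + 2.0 * np.clip(t_true - 0.7, 0, None) / 0.3
        s_mean[:, murk_idx] *= boost[:, None]
        u_mean[:, murk_idx] *= boost[:, None]
        classes = classes.copy()
        classes[murk_idx] = "induction"
    else:
        murk_idx = np.array([], dtype=int)

    sd = spec.noise_sd * params.h
    s_obs = np.clip(s_mean + rng.normal(0.0, 1.0, s_mean.shape) * sd, 0.0, None)
    u_obs = np.clip(u_mean + rng.normal(0.0, 1.0, u_mean.shape) * sd, 0.0, None)

    edges = np.linspace(0.0, 1.0, spec.n_clusters + 1)
    bins = np.clip(np.digitize(t_true, edges[1:-1]), 0, spec.n_clusters - 1)
    labels = pd.Categorical(
        [f"bin_{k}" for k in bins],
        categories=[f"bin_{k}" for k in range(spec.n_clusters)],
    )
    transitions = [(f"bin_{k}", f"bin_{k + 1}") for k in range(spec.n_clusters - 1)]

    obs = pd.DataFrame(
        {"clusters": labels, "true_time": t_true},
        index=[f"cell_{n}" for n in range(spec.n_cells)],
    )
    var = pd.DataFrame(
        {"true_class": classes, "true_tau": params.tau},
        index=[f"gene_{j}" for j in range(spec.n_genes)],
    )

    adata = AnnData(X=s_obs.copy(), obs=obs, var=var)
    adata.layers["spliced"] = s_obs
    adata.layers["unspliced"] = u_obs
    adata.uns["truth"] = {
        "time": t_true,
        "params": {
            "h": params.h, "a": params.a, "tau": params.tau,
            "gamma": params.gamma, "beta": params.beta,
            "o": params.o, "i": params.i,
        },
        "velocity": vel_true,
        "gene_class": classes,
        "transitions": transitions,
        "murk_genes": murk_idx,
    }
    return adata
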