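"""Reading and writing annotated expression containers.

Supported inputs: ``.h5ad`` (AnnData), or a directory of MTX triplets
(``spliced.mtx``, ``unspliced.mtx``) with sidecar ``obs.tsv`` /
``var.tsv`` metadata tables.  Outputs are written as ``.h5ad``.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio

__all__ = ["read_dataset", "write_dataset"]

REQUIRED_LAYERS = ("spliced", "unspliced")


def _check_layers(adata: AnnData) -> AnnData:
    missing = [k for k in REQUIRED_LAYERS if k not in adata.layers]
    if missing:
        raise KeyError(
            f"input container is missing required layer(s) {missing}; "
            f"expected cell-by-gene layers named {list(REQUIRED_LAYERS)}"
        )
    return adata


def read_dataset(path) -> AnnData:
    """Read an annotated dataset with spliced/unspliced layers.

    ``path`` may be an ``.h5ad`` file or a directory containing
    ``spliced.mtx``, ``unspliced.mtx`` and optional tab-separated
    ``obs.tsv`` / ``var.tsv`` tables (first column = index).
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        return _check_layers(ad.read_h5ad(path))
    if suffix == ".loom":
        raise NotImplementedError(
            "loom input is not supported in this build; convert to .h5ad "
            "or provide an MTX triplet directory"
        )
    raise ValueError(f"unrecognized input format: {path}")


def _read_mtx_dir(path: Path) -> AnnData:
    spliced_f = path / "spliced.mtx"
    unspliced_f = path / "unspliced.mtx"
    for f in (spliced_f, unspliced_f):
        if not f.exists():
            raise FileNotFoundError(f"expected {f.name} in {path}")
    def _mm(f):
        m = spio.mmread(f)
        return np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)

    s = _mm(spliced_f)
    u = _mm(unspliced_f)
    if s.shape != u.shape:
        raise ValueError(f"layer shape mismatch: spliced {s.shape} vs unspliced {u.shape}")

    def _table(name, n, prefix):
        f = path / name
        if f.exists():
            return pd.read_csv(f, sep="\t", index_col=0)
        return pd.DataFrame(index=[f"{prefix}{k}" for k in range(n)])

    obs = _table("obs.tsv", s.shape[0], "cell_")
    var = _table("var.tsv", s.shape[1], "gene_")
    adata = AnnData(X=s.copy(), obs=obs, var=var)
    adata.layers["spliced"] = s
    adata.layers["unspliced"] = u
    return _check_layers(adata)


def write_dataset(adata: AnnData, path) -> None:
    """Write the (annotated, possibly fitted) dataset to ``.h5ad``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = adata.copy()
    # h5ad cannot hold arbitrary python objects; stringify the truth block
    if "truth" in out.uns:
        del out.uns["truth"]
    out.write_h5ad(path)
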