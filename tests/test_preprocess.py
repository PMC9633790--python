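"""Filtering, normalization, smoothing and velocity-gene selection."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from rbfvelo.preprocess import (
    amplify_velocity_genes,
    knn_moments,
    normalize_and_filter,
    select_hvg,
    select_velocity_genes,
)


def make_adata(s, u, genes=None):
    s, u = np.asarray(s, float), np.asarray(u, float)
    genes = genes or [f"g{j}" for j in range(s.shape[1])]
    ad = AnnData(
        X=s.copy(),
        obs=pd.DataFrame(index=[f"c{n}" for n in range(s.shape[0])]),
        var=pd.DataFrame(index=genes),
    )
    ad.layers["spliced"] = s
    ad.layers["unspliced"] = u
    return ad


class TestNormalizeAndFilter:
    def test_drops_genes_below_min_cells(self):
        # gene 2 has unspliced counts in only one cell
        s = np.ones((5, 3))
        u = np.ones((5, 3))
        u[1:, 2] = 0.0
        ad = make_adata(s, u)
        normalize_and_filter(ad, min_cells=2)
        assert list(ad.var_names) == ["g0", "g1"]

    def test_all_zero_gene_always_dropped(self):
        s = np.random.default_rng(0).poisson(5, (30, 4)).astype(float)
        u = s.copy()
        s[:, 3] = 0.0
        ad = make_adata(s, u)
        normalize_and_filter(ad, min_cells=1)
        assert "g3" not in ad.var_names

    def test_normalization_preserves_proportions_and_totals(self):
        rng = np.random.default_rng(1)
        s = rng.poisson(10, (25, 6)).astype(float) + 1
        u = rng.poisson(3, (25, 6)).astype(float) + 1
        ad = make_adata(s, u)
        normalize_and_filter(ad, min_cells=1)
        norm = ad.layers["spliced_norm"]
        # every cell total equals the median raw total
        np.testing.assert_allclose(norm.sum(axis=1), np.median(s.sum(axis=1)))
        # within-cell proportions unchanged
        np.testing.assert_allclose(
            norm / norm.sum(1, keepdims=True), s / s.sum(1, keepdims=True)
        )

    def test_empty_result_is_informative(self):
        ad = make_adata(np.zeros((5, 2)), np.zeros((5, 2)))
        with pytest.raises(ValueError, match="no gene"):
            normalize_and_filter(ad, min_cells=1)


class TestSelectHVG:
    def test_small_dataset_keeps_all(self):
        rng = np.random.default_rng(2)
        ad = make_adata(rng.poisson(5, (30, 10)) + 1.0, rng.poisson(2, (30, 10)) + 1.0)
        normalize_and_filter(ad, min_cells=1)
        mask = select_hvg(ad, n_top=2000)
        assert mask.all()

    def test_variable_gene_beats_constant(self):
        rng = np.random.default_rng(3)
        var = rng.uniform(1, 50, 40)
        # constant cell totals so normalization leaves the layer unchanged
        s = np.column_stack([np.full(40, 5.0), var, 60.0 - var])
        ad = make_adata(s, s.copy())
        normalize_and_filter(ad, min_cells=1)
        mask = select_hvg(ad, n_top=1)
        assert not mask[0]
        assert mask.sum() == 1


class TestKnnMoments:
    def test_identical_cells_are_unchanged(self):
        s = np.tile([2.0, 4.0, 1.0], (25, 1))
        ad = make_adata(s, s * 0.5)
        normalize_and_filter(ad, min_cells=1)
        knn_moments(ad, n_pcs=2, n_neighbors=5)
        np.testing.assert_allclose(ad.layers["Ms"], ad.layers["spliced_norm"])
        np.testing.assert_allclose(ad.layers["Mu"], ad.layers["unspliced_norm"])

    def test_k1_is_identity(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(1, 10, (20, 5))
        ad = make_adata(s, s * 0.3)
        normalize_and_filter(ad, min_cells=1)
        knn_moments(ad, n_pcs=3, n_neighbors=1)
        np.testing.assert_allclose(ad.layers["Ms"], ad.layers["spliced_norm"])

    def test_means_match_brute_force_over_neighbors(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(1, 10, (15, 4))
        ad = make_adata(s, s * 0.4)
        normalize_and_filter(ad, min_cells=1)
        knn_moments(ad, n_pcs=3, n_neighbors=4)
        idx = ad.obsm["knn_indices"]
        expected = ad.layers["spliced_norm"][idx].mean(axis=1)
        np.testing.assert_allclose(ad.layers["Ms"], expected)

    def test_too_few_cells_reduces_k(self):
        s = np.random.default_rng(6).uniform(1, 5, (8, 4))
        ad = make_adata(s, s)
        normalize_and_filter(ad, min_cells=1)
        knn_moments(ad, n_pcs=2, n_neighbors=30)
        assert ad.obsm["knn_indices"].shape[1] == 8


class TestSelectVelocityGenes:
    def toy(self):
        """8 genes engineered around the slope / R2 / sigma-ratio filters."""
        rng = np.random.default_rng(7)
        n = 200
        s = rng.uniform(1, 4, n)
        cols_s, cols_u, keep = [], [], []
        # 0: u = 0.5 s exactly -> kept
        cols_s.append(s); cols_u.append(0.5 * s); keep.append(True)
        # 1: negative slope -> dropped
        cols_s.append(s); cols_u.append(np.maximum(3 - 0.8 * s, 0)); keep.append(False)
        # 2: sd ratio 5 -> dropped (u = 5*(s - mean) + 5*mean keeps slope>0)
        cols_s.append(s); cols_u.append(5.0 * s); keep.append(False)
        # 3: sd ratio ~0.01 -> dropped (u nearly constant but positive slope)
        cols_s.append(s); cols_u.append(0.01 * s + 1.0); keep.append(False)
        # 4: pure noise u, slope ~0 R2 ~0 -> dropped
        cols_s.append(s); cols_u.append(rng.normal(2.0, 1e-3, n)); keep.append(False)
        # 5: u = 2 s, ratio 2, kept
        cols_s.append(s); cols_u.append(2.0 * s); keep.append(True)
        # 6: zero-variance spliced -> excluded (undefined ratio)
        cols_s.append(np.full(n, 2.0)); cols_u.append(rng.uniform(1, 2, n)); keep.append(False)
        # 7: u = 0.2 s with mild noise -> kept
        cols_s.append(s); cols_u.append(0.2 * s + rng.normal(0, 0.01, n)); keep.append(True)
        ms = np.column_stack(cols_s)
        mu = np.column_stack(cols_u)
        ad = make_adata(ms, mu)
        ad.layers["Ms"], ad.layers["Mu"] = ms, mu
        ad.var["highly_variable"] = True
        return ad, np.array(keep)

    def test_toy_matrix_filters_exactly(self):
        ad, keep = self.toy()
        mask = select_velocity_genes(ad)
        np.testing.assert_array_equal(mask, keep)

    def test_invariant_to_gene_order(self):
        ad, keep = self.toy()
        perm = np.random.default_rng(8).permutation(ad.n_vars)
        ad2 = ad[:, perm].copy()
        mask2 = select_velocity_genes(ad2)
        np.testing.assert_array_equal(mask2, keep[perm])


class TestAmplifyVelocityGenes:
    def base(self, n=150):
        rng = np.random.default_rng(9)
        t = rng.uniform(0, 1, n)
        ms = np.column_stack([
            2.0 + 3.0 * t,                  # perfectly linear in time
            rng.normal(2.0, 1.0, n),        # pure noise
            1.0 + 0.5 * t,                  # linear, already selected
        ])
        ad = make_adata(ms, ms * 0.5)
        ad.layers["Ms"], ad.layers["Mu"] = ms, ms * 0.5
        ad.var["highly_variable"] = True
        ad.var["velocity_genes"] = np.array([False, False, True])
        return ad, t

    def test_time_linear_gene_added_noise_gene_not(self):
        ad, t = self.base()
        mask = amplify_velocity_genes(ad, t, r2_threshold=0.5)
        assert mask[0] and mask[2]
        assert not mask[1]

    def test_independent_mode_noop(self):
        ad, t = self.base()
        tmat = np.tile(t[:, None], (1, 3))
        mask = amplify_velocity_genes(ad, tmat, r2_threshold=0.5)
        np.testing.assert_array_equal(mask, [False, False, True])
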