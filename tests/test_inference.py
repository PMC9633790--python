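"""Alternating optimization: init, gradients, time assignment, unification."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import rbfvelo.inference as inf
from rbfvelo.inference import (
    AdamState,
    FitConfig,
    assign_time,
    fit,
    gradient_step,
    init_params,
    unify_time,
)
from rbfvelo.model import GeneParams, LatentTime, spliced_mean, unspliced_mean

from conftest import random_gene_params


class TestInitParams:
    def test_tau_starts_at_half_and_is_deterministic(self, prepared_sim):
        p1, t1 = init_params(prepared_sim, seed=3)
        p2, t2 = init_params(prepared_sim, seed=3)
        assert np.all(p1.tau == 0.5)
        np.testing.assert_array_equal(p1.h, p2.h)
        np.testing.assert_array_equal(t1.t, t2.t)

    def test_amplitude_from_data_range(self, prepared_sim):
        p, _ = init_params(prepared_sim)
        ms = np.asarray(prepared_sim.layers["Ms"])[
            :, prepared_sim.var["velocity_genes"].to_numpy()
        ]
        np.testing.assert_allclose(p.h, np.maximum(ms.max(0) - ms.min(0), 1e-3))
        np.testing.assert_allclose(p.o, ms.min(0))

    def test_independent_mode_zero_offsets(self, prepared_sim):
        p, t = init_params(prepared_sim, mode="independent")
        assert np.all(p.o == 0) and np.all(p.i == 0)
        assert t.mode == "independent" and t.t.ndim == 2


class TestGradientStep:
    def test_zero_learning_rate_is_identity(self):
        rng = np.random.default_rng(0)
        p = random_gene_params(rng, g=4)
        t = rng.uniform(0, 1, 30)
        mu, ms = rng.uniform(0, 2, (30, 4)), rng.uniform(0, 2, (30, 4))
        p2, _ = gradient_step(p, mu, ms, t, AdamState(), learning_rate=0.0)
        np.testing.assert_array_equal(p2.tau, p.tau)
        # positive parameters round-trip through log space: bit-level noise only
        np.testing.assert_allclose(p2.h, p.h, rtol=1e-14)
        np.testing.assert_allclose(p2.gamma, p.gamma, rtol=1e-14)

    def test_matches_finite_difference_gradient(self):
        """Analytic gradients agree with central differences of the loss."""
        rng = np.random.default_rng(1)
        p = random_gene_params(rng, g=3)
        t = rng.uniform(0, 1, 25)
        mu, ms = rng.uniform(0, 2, (25, 3)), rng.uniform(0, 2, (25, 3))
        theta = inf._unconstrained(p, inf._FREE)
        _, grads = inf._loss_and_grads(theta, p, mu, ms, t, inf._FREE)
        eps = 1e-6
        for name in inf._FREE:
            for j in range(3):
                th = {k: v.copy() for k, v in theta.items()}
                th[name][j] += eps
                lp, _ = inf._loss_and_grads(th, p, mu, ms, t, inf._FREE)
                th[name][j] -= 2 * eps
                lm, _ = inf._loss_and_grads(th, p, mu, ms, t, inf._FREE)
                fd = (lp.sum() - lm.sum()) / (2 * eps)
                assert grads[name][j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_converges_to_least_squares_offset(self):
        """With only the offset free, Adam reaches the analytic minimizer."""
        rng = np.random.default_rng(2)
        p = random_gene_params(rng, g=1)
        t = rng.uniform(0, 1, 50)
        shift = 0.7
        o0 = p.o[0]
        ms = spliced_mean(p, t)[:, 0] + shift
        mu = unspliced_mean(p, t)[:, 0] + p.gamma[0] / p.beta[0] * shift
        state = AdamState()
        for _ in range(500):
            p, _ = gradient_step(p, mu[:, None], ms[:, None], t, state,
                                 learning_rate=0.05, free=("o",))
        # analytic (least-squares) minimum: the offset absorbs the shift
        assert p.o[0] == pytest.approx(o0 + shift, abs=1e-3)

    def test_loss_decreases_on_simulated_data(self, prepared_sim):
        mu, ms, _ = inf._get_layers(prepared_sim)
        p, time = init_params(prepared_sim)
        state = AdamState()
        p, loss0 = gradient_step(p, mu, ms, time, state)
        for _ in range(100):
            p, loss = gradient_step(p, mu, ms, time, state)
        assert loss.sum() < loss0.sum()

    def test_nonfinite_gradient_names_gene(self):
        p = GeneParams(h=1.0, a=1.0, tau=0.5, gamma=1.0, beta=1.0)
        t = np.array([0.5])
        with pytest.raises((FloatingPointError, ValueError)):
            gradient_step(p, np.array([[np.inf]]), np.array([[1.0]]), t, AdamState())


class TestAssignTime:
    def test_recovers_exact_grid_point(self):
        rng = np.random.default_rng(3)
        p = random_gene_params(rng, g=5)
        grid = np.linspace(0, 1, 100)
        t_star = grid[37]
        mu = unspliced_mean(p, np.array([t_star]))
        ms = spliced_mean(p, np.array([t_star]))
        t_ng = assign_time(p, mu, ms, grid_size=100)
        np.testing.assert_allclose(t_ng, t_star)

    def test_two_point_grid_assigns_nearer_endpoint(self):
        p = GeneParams(h=2.0, a=3.0, tau=1.0, gamma=1.0, beta=1.0)  # rising on [0,1]
        t_true = np.array([0.05, 0.95])
        mu, ms = unspliced_mean(p, t_true), spliced_mean(p, t_true)
        t_ng = assign_time(p, mu, ms, grid_size=2)
        np.testing.assert_array_equal(t_ng.ravel(), [0.0, 1.0])

    def test_matches_brute_force_fine_grid(self):
        """Grid argmin equals exhaustive search within one grid step."""
        rng = np.random.default_rng(4)
        p = random_gene_params(rng, g=20)
        t_true = rng.uniform(0, 1, 30)
        mu = unspliced_mean(p, t_true) + rng.normal(0, 0.05, (30, 20))
        ms = spliced_mean(p, t_true) + rng.normal(0, 0.05, (30, 20))
        t_fast = assign_time(p, mu, ms, grid_size=1000)
        fine = np.linspace(0, 1, 10000)
        uc, sc = unspliced_mean(p, fine), spliced_mean(p, fine)
        for j in range(20):
            d = (mu[:, j, None] - uc[None, :, j]) ** 2 + (ms[:, j, None] - sc[None, :, j]) ** 2
            t_brute = fine[np.argmin(d, axis=1)]
            assert np.max(np.abs(t_fast[:, j] - t_brute)) <= 1.0 / 999 + 1e-12


class TestUnifyTime:
    def test_identical_orderings_reproduced(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 1, 50)
        t_ng = np.tile(base[:, None], (1, 10))
        t = unify_time(t_ng, denoise_dims=0)
        assert spearmanr(t, base).statistic == pytest.approx(1.0)

    def test_reversed_orderings_cancel(self):
        base = np.linspace(0, 1, 40)
        t_ng = np.column_stack([base, 1 - base])
        t = unify_time(t_ng, denoise_dims=0)
        # complete cancellation: all cells collapse to the same value
        assert np.allclose(t, t[0])

    def test_single_gene_equals_quantile_transform(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0, 1, 30)
        t = unify_time(base[:, None], denoise_dims=0)
        assert spearmanr(t, base).statistic == pytest.approx(1.0)

    def test_averaging_beats_single_noisy_gene(self):
        """Pooling 50 noisy copies recovers the latent order better."""
        rng = np.random.default_rng(7)
        latent = rng.uniform(0, 1, 80)
        wins = 0
        for _ in range(20):
            t_ng = latent[:, None] + rng.normal(0, 0.25, (80, 50))
            pooled = unify_time(t_ng, denoise_dims=0)
            rho_pool = abs(spearmanr(pooled, latent).statistic)
            rho_single = np.mean([
                abs(spearmanr(t_ng[:, j], latent).statistic) for j in range(50)
            ])
            wins += rho_pool > rho_single
        assert wins >= 19


class TestFit:
    def test_independent_mode_contract(self, prepared_sim):
        """(tau, o, i) stay fixed at (0.5, 0, 0) in independent mode."""
        cfg = FitConfig(max_iters=60, warmup=10, mode="independent", seed=0)
        res = fit(prepared_sim, cfg)
        assert np.all(res.params.tau == 0.5)
        assert np.all(res.params.o == 0.0)
        assert np.all(res.params.i == 0.0)
        assert res.time.mode == "independent"

    def test_unified_time_shared_and_bounded(self, prepared_sim):
        cfg = FitConfig(max_iters=120, warmup=30, pilot_iters=20, seed=0)
        res = fit(prepared_sim, cfg)
        assert res.time.mode == "unified"
        assert res.time.t.shape == (prepared_sim.n_obs,)
        assert res.time.t.min() >= 0 and res.time.t.max() <= 1
        assert np.isfinite(res.velocity_matrix).all()

    def test_loss_trace_decreases_overall(self, prepared_sim):
        cfg = FitConfig(max_iters=200, warmup=50, pilot_iters=0, seed=0)
        res = fit(prepared_sim, cfg)
        assert res.loss_trace[-1] <= res.loss_trace[0]
        assert len(res.loss_trace) <= cfg.max_iters

    def test_deterministic_given_seed(self, prepared_sim):
        cfg = FitConfig(max_iters=80, warmup=20, pilot_iters=10, seed=5)
        r1 = fit(prepared_sim, cfg)
        r2 = fit(prepared_sim, cfg)
        np.testing.assert_array_equal(r1.time.t, r2.time.t)
        np.testing.assert_array_equal(r1.velocity_matrix, r2.velocity_matrix)


class TestFitConfigValidation:
    @pytest.mark.parametrize(
        "kw", [dict(conv_tol=0), dict(grid_size=1), dict(reassign_every=0),
               dict(mode="other")],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            FitConfig(**kw)
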