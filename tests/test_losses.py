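"""Every objective component against a hand or naive-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmadapt import (
    ModelConfig,
    adversarial_loss,
    aleatoric_loss,
    bnn_task_loss,
    init_model,
    mtl_loss,
    reconstruction_loss,
    task_mse,
    total_loss,
    transfer_weight,
)
from pharmadapt.model import forward


class TestAleatoricLoss:
    def test_unit_sigma_plugin(self):
        assert aleatoric_loss(1.0, 1.0) == pytest.approx(0.5)
        assert aleatoric_loss(0.0, 1.0) == pytest.approx(0.0)

    def test_grid_minimizer_is_sqrt_mse(self):
        """For mse = 4 the attenuation is minimized at sigma = 2."""
        grid = np.arange(0.05, 5.0, 0.01)
        vals = [aleatoric_loss(4.0, s) for s in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(2.0, abs=0.011)

    def test_monotone_on_either_side_of_minimum(self):
        below = [aleatoric_loss(4.0, s) for s in (0.5, 1.0, 1.5, 1.9)]
        above = [aleatoric_loss(4.0, s) for s in (2.1, 3.0, 4.0, 6.0)]
        assert np.all(np.diff(below) < 0) and np.all(np.diff(above) > 0)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            aleatoric_loss(1.0, 0.0)


class TestBnnTaskLoss:
    def test_perfect_predictions_unit_sigma(self):
        y = np.arange(6.0).reshape(3, 2)
        out = bnn_task_loss(y, y, np.ones((3, 2), bool), np.zeros(2))
        assert np.allclose(out, 0.0)

    def test_hand_arithmetic_single_task(self):
        pred = np.array([[1.0], [-1.0]])
        y = np.zeros((2, 1))
        out = bnn_task_loss(pred, y, np.ones((2, 1), bool), np.zeros(1))
        assert out[0] == pytest.approx(0.5)  # mse 1, sigma 1

    def test_matches_naive_loop_oracle(self, rng):
        n, T = 9, 4
        pred = rng.standard_normal((n, T))
        y = rng.standard_normal((n, T))
        mask = rng.random((n, T)) < 0.7
        mask[0] = True
        ls = rng.normal(0, 0.5, T)
        out = bnn_task_loss(pred, y, mask, ls)
        for t in range(T):
            se, c = 0.0, 0
            for i in range(n):
                if mask[i, t]:
                    se += (pred[i, t] - y[i, t]) ** 2
                    c += 1
            expect = se / c / (2 * np.exp(ls[t]) ** 2) + ls[t]
            assert out[t] == pytest.approx(expect, abs=1e-9)

    def test_fully_masked_task_contributes_zero(self):
        pred = np.ones((2, 2))
        y = np.zeros((2, 2))
        mask = np.array([[True, False], [True, False]])
        with pytest.warns(UserWarning, match="all-masked"):
            out = bnn_task_loss(pred, y, mask, np.zeros(2))
        assert out[1] == 0.0 and out[0] > 0


class TestTransferWeight:
    def test_degenerate_inputs_give_unit_weight(self):
        U = np.zeros(3)
        A = np.zeros((3, 4))
        for mode in ("product", "sum"):
            assert np.allclose(transfer_weight(U, A, mode), 1.0)

    def test_hand_arithmetic_both_modes(self):
        U = np.array([2.0])
        A = np.array([[0.5, -0.5]])
        assert transfer_weight(U, A, "product")[0] == pytest.approx(3.0)
        assert transfer_weight(U, A, "sum")[0] == pytest.approx(4.0)

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            transfer_weight(np.array([-0.1]), np.zeros((1, 2)))


class TestReconstructionLoss:
    def test_identity_composition_reconstructs(self):
        Z = np.abs(np.random.default_rng(0).standard_normal((5, 3)))
        S = np.eye(3)
        A = np.eye(3)
        assert reconstruction_loss(Z, S, A, gamma=2.0) == pytest.approx(0.0)

    def test_zero_latent_is_free(self, rng):
        S = rng.standard_normal((3, 4))
        A = rng.standard_normal((4, 3))
        assert reconstruction_loss(np.zeros((6, 3)), S, A, 1.0) == 0.0

    def test_matches_elementwise_loop(self, rng):
        Z = rng.standard_normal((4, 3))
        S = rng.standard_normal((3, 5))
        A = rng.standard_normal((5, 3))
        gamma = 0.7
        recon = np.maximum(Z @ S @ A, 0)
        total = 0.0
        for i in range(4):
            for j in range(3):
                total += (Z[i, j] - recon[i, j]) ** 2
        assert reconstruction_loss(Z, S, A, gamma) == pytest.approx(
            gamma * total, abs=1e-9
        )


class TestAdversarialLoss:
    def test_maximal_confusion_value(self):
        p = np.full(8, 0.5)
        assert adversarial_loss(p, p) == pytest.approx(2 * np.log(2))

    def test_perfect_discrimination_limit(self):
        assert adversarial_loss(np.array([1.0 - 1e-9]), np.array([1e-9])) < 1e-6

    def test_hand_arithmetic(self):
        got = adversarial_loss(np.array([0.8]), np.array([0.3]))
        assert got == pytest.approx(-np.log(0.8) - np.log(0.7), abs=1e-9)

    def test_clamps_degenerate_probabilities(self):
        assert np.isfinite(adversarial_loss(np.array([0.0]), np.array([1.0])))


class TestTotalLoss:
    def test_zero_adversarial_weight(self):
        assert total_loss(2.0, 1.3863, 0.0) == 2.0

    def test_weighted_sum(self):
        assert total_loss(2.0, 1.3863, 0.5) == pytest.approx(2.69315)

    def test_affine_in_lam_adv(self):
        vals = [total_loss(1.0, 2.0, lam) for lam in (0.0, 0.5, 1.0, 1.5)]
        assert np.allclose(np.diff(vals), 1.0)


class TestMtlLossComposition:
    def _setup(self, rng, **cfg_kw):
        cfg = ModelConfig(n_latent=3, seed=2, **cfg_kw)
        params = init_model(cfg, 6, 4)
        X = rng.standard_normal((8, 6))
        Y = rng.standard_normal((8, 4))
        mask = rng.random((8, 4)) < 0.8
        mask[0] = True
        return cfg, params, (X, Y, mask)

    def test_degenerate_hyperparameters_reduce_to_task_losses(self, rng):
        cfg, params, batch = self._setup(
            rng, mu=0.0, lam=0.0, gamma=0.0, dropout_rate=0.0
        )
        params.A = np.zeros_like(params.A)
        bd = mtl_loss(batch, params, cfg, U=np.zeros(4))
        assert bd.total == pytest.approx(np.sum(bd.per_task_bnn), abs=1e-12)

    def test_doubling_mu_doubles_only_l1(self, rng):
        cfg, params, batch = self._setup(rng, mu=0.01, dropout_rate=0.0)
        bd1 = mtl_loss(batch, params, cfg, U=np.zeros(4))
        bd2 = mtl_loss(batch, params, cfg.with_(mu=0.02), U=np.zeros(4))
        assert np.allclose(bd2.l1_s, 2 * bd1.l1_s)
        assert np.allclose(bd2.per_task_bnn, bd1.per_task_bnn)
        assert bd2.recon == bd1.recon and bd2.l2_L == bd1.l2_L

    def test_total_recomposes_from_components(self, rng):
        cfg, params, batch = self._setup(
            rng, mu=0.01, lam=0.02, gamma=0.5, dropout_rate=0.0
        )
        U = np.abs(rng.standard_normal(4))
        bd = mtl_loss(batch, params, cfg, U=U)
        X, Y, mask = batch
        pred, cache = forward(X, params, cfg)
        expect = (
            np.sum(
                transfer_weight(U, params.A)
                * bnn_task_loss(pred, Y, mask, params.log_sigma)
            )
            + cfg.mu * np.abs(params.S).sum()
            + reconstruction_loss(cache["Zd"], params.S, params.A, cfg.gamma)
            + cfg.lam * np.sum(params.L**2)
        )
        assert bd.total == pytest.approx(expect, abs=1e-6)

    def test_invariant_under_task_permutation(self, rng):
        cfg, params, (X, Y, mask) = self._setup(rng, dropout_rate=0.0)
        U = np.abs(rng.standard_normal(4))
        bd = mtl_loss((X, Y, mask), params, cfg, U=U)
        perm = np.array([2, 0, 3, 1])
        import copy

        p2 = copy.deepcopy(params)
        p2.S = params.S[:, perm]
        p2.bS = params.bS[perm]
        p2.A = params.A[perm]
        p2.log_sigma = params.log_sigma[perm]
        bd2 = mtl_loss((X, Y[:, perm], mask[:, perm]), p2, cfg, U=U[perm])
        assert np.allclose(bd2.per_task_bnn, bd.per_task_bnn[perm], atol=1e-10)
        assert bd2.total == pytest.approx(bd.total, abs=1e-8)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    u=st.lists(st.floats(0, 10), min_size=1, max_size=6),
    scale=st.floats(0.1, 5),
)
def test_transfer_weight_bounds(u, scale):
    """Gate is always >= 1 and increases with uncertainty (fixed decoder)."""
    U = np.array(u)
    A = np.full((len(u), 3), scale)
    for mode in ("product", "sum"):
        w = transfer_weight(U, A, mode)
        assert np.all(w >= 1.0)
        w2 = transfer_weight(U + 1.0, A, mode)
        assert np.all(w2 >= w)
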