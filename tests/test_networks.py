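"""Autoencoder losses, GAT algebra, GAE training, cluster/imputation AEs."""

import numpy as np
import pytest

from scgraphae import (
    FeatureAEConfig,
    ImputationLossConfig,
    attention_coefficients,
    feature_ae_loss,
    gae_decode,
    gae_loss,
    gat_layer,
    imputation_loss,
    train_cluster_ae,
    train_feature_ae,
    train_gae,
    train_imputation_ae,
)
from scgraphae.cellgraph import build_knn_graph, normalize_adjacency, prune_graph


class TestFeatureAELoss:
    def test_zero_at_perfect_reconstruction(self, rng):
        x = rng.normal(size=(3, 4))
        w = rng.random((3, 4))
        for alpha in (0.0, 0.3, 1.0):
            assert feature_ae_loss(x, x, w, alpha) == 0.0

    def test_plain_mse_when_alpha_zero(self):
        x = np.ones((2, 2))
        assert feature_ae_loss(x, np.zeros((2, 2)), np.zeros((2, 2)), 0.0) == 4.0

    def test_matches_scalar_loop(self, rng):
        x, xh, w = rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), rng.random((3, 3))
        alpha = 0.3
        oracle = sum(
            (1 - alpha) * (x[i, j] - xh[i, j]) ** 2
            + alpha * (x[i, j] - xh[i, j]) ** 2 * w[i, j]
            for i in range(3)
            for j in range(3)
        )
        assert feature_ae_loss(x, xh, w, alpha) == pytest.approx(oracle, rel=1e-12)


class TestTrainFeatureAE:
    def test_low_rank_recoverable(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.random((1, 20)) * 2
        x = np.abs(u @ v) + rng.normal(scale=0.01, size=(30, 20))
        cfg = FeatureAEConfig(hidden_dim=32, latent_dim=8, epochs=200, alpha=0.0, seed=0)
        _, xhat, trace = train_feature_ae(x, np.ones_like(x), cfg)
        assert trace[-1] <= trace[0]
        mse = ((x - xhat.values) ** 2).mean()
        assert mse < 0.1 * x.var()

    def test_zero_matrix_fixed_point(self):
        x = np.zeros((10, 5))
        cfg = FeatureAEConfig(hidden_dim=8, latent_dim=4, epochs=100, alpha=0.0, seed=0)
        _, _, trace = train_feature_ae(x, np.ones_like(x), cfg)
        assert trace[-1] < 1e-4

    def test_deterministic_given_seed(self, rng):
        x = rng.random((12, 6))
        cfg = FeatureAEConfig(hidden_dim=8, latent_dim=4, epochs=30, alpha=0.5, seed=7)
        w = rng.random(x.shape)
        r1 = train_feature_ae(x, w, cfg)
        r2 = train_feature_ae(x, w, cfg)
        np.testing.assert_array_equal(r1[2], r2[2])  # bit-identical loss trajectory
        np.testing.assert_array_equal(r1[1].values, r2[1].values)


class TestAttention:
    def test_identical_rows_give_uniform(self):
        h = np.ones((4, 3))
        w = np.eye(3)
        mask = np.ones((4, 4), bool)
        a = attention_coefficients(h, w, mask)
        np.testing.assert_allclose(a, 0.25)

    def test_single_neighbor_is_one(self):
        h = np.random.default_rng(0).normal(size=(3, 2))
        mask = np.eye(3, dtype=bool)
        mask[0, 1] = True
        a = attention_coefficients(h, np.eye(2), mask)
        np.testing.assert_allclose(a[1, 1], 1.0)
        np.testing.assert_allclose(a[0, [0, 1]].sum(), 1.0)

    def test_matches_exp_normalize_oracle(self, rng):
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 2))
        mask = np.ones((4, 4), bool)
        a = attention_coefficients(h, w, mask)
        m = h @ w
        scores = m @ m.T
        for i in range(4):
            ex = np.exp(scores[i] - scores[i].max())
            np.testing.assert_allclose(a[i], ex / ex.sum(), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        h = rng.normal(size=(6, 4))
        w = rng.normal(size=(4, 3))
        mask = (rng.random((6, 6)) < 0.5) | np.eye(6, dtype=bool)
        mask = mask | mask.T
        a = attention_coefficients(h, w, mask)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(a[~mask] == 0)


class TestGATLayer:
    def test_heads_zero_equals_dense_oracle(self, rng):
        h = rng.normal(size=(5, 4))
        w = rng.normal(size=(4, 3))
        a = rng.random((5, 5))
        out = gat_layer(h, a, heads=0, w_heads=[w])
        np.testing.assert_allclose(out, np.maximum(a @ h @ w, 0.0), atol=1e-12)

    def test_multi_head_is_mean_of_single_heads(self, rng):
        h = rng.normal(size=(5, 4))
        ws = [rng.normal(size=(4, 3)) for _ in range(3)]
        adj = (rng.random((5, 5)) < 0.6).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        ident = lambda z: z
        singles = [gat_layer(h, adj, 1, [w], activation=ident) for w in ws]
        combined = gat_layer(h, adj, 3, ws, activation=ident)
        np.testing.assert_allclose(combined, np.mean(singles, axis=0), atol=1e-10)

    def test_uniform_attention_symmetric_output(self):
        h = np.ones((4, 2))
        w = np.full((2, 2), 0.5)
        adj = 1 - np.eye(4)
        out = gat_layer(h, adj, heads=1, w_heads=[w])
        assert np.allclose(out, out[0])


class TestGAEDecodeLoss:
    def test_zero_embedding_gives_half(self):
        out = gae_decode(np.zeros((3, 2))).values
        np.testing.assert_allclose(out, 0.5)

    def test_orthogonal_embeddings(self):
        z = np.eye(3) * 10
        out = gae_decode(z).values
        assert np.all(np.diag(out) > 0.99)
        off = out[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_decode_matches_scalar_sigmoid(self, rng):
        z = rng.normal(size=(4, 2))
        out = gae_decode(z).values
        for i in range(4):
            for j in range(4):
                s = z[i] @ z[j]
                np.testing.assert_allclose(out[i, j], 1 / (1 + np.exp(-s)), atol=1e-12)

    def test_loss_closed_form(self):
        a = np.ones((2, 2))
        ahat = np.full((2, 2), 0.5)
        assert gae_loss(a, ahat) == pytest.approx(np.log(2), rel=1e-9)

    def test_loss_matches_scalar_oracle(self, rng):
        a = (rng.random((3, 3)) < 0.5).astype(float)
        ahat = rng.uniform(0.05, 0.95, size=(3, 3))
        oracle = -np.mean(
            [
                a[i, j] * np.log(ahat[i, j]) + (1 - a[i, j]) * np.log(1 - ahat[i, j])
                for i in range(3)
                for j in range(3)
            ]
        )
        assert gae_loss(a, ahat) == pytest.approx(oracle, rel=1e-10)

    def test_near_perfect_reconstruction_near_zero(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        ahat = np.clip(a, 1e-7, 1 - 1e-7)
        assert gae_loss(a, ahat) < 1e-5


class TestTrainGAE:
    def _blob_graph(self, seed=3):
        r = np.random.default_rng(seed)
        emb = np.vstack([r.normal(0, 0.3, (15, 5)), r.normal(4, 0.3, (15, 5))])
        g = build_knn_graph(emb, 5)
        gp = prune_graph(g, emb, 0.9)
        return emb, gp, normalize_adjacency(gp)

    def test_planted_blob_recovery(self):
        emb, gp, atil = self._blob_graph()
        ge = train_gae(atil, emb, gp.adjacency, heads=3, epochs=150, seed=0)
        assert ge.loss_trace[-1] < ge.loss_trace[0]
        ahat = gae_decode(ge.Z).values
        within = gp.adjacency.copy()
        within[:15, 15:] = 0
        within[15:, :15] = 0
        assert (ahat > 0.5)[within > 0].mean() >= 0.9

    def test_zero_epochs_returns_initial_forward(self):
        emb, gp, atil = self._blob_graph()
        ge = train_gae(atil, emb, gp.adjacency, heads=1, epochs=0, seed=5)
        assert len(ge.loss_trace) == 1
        assert np.isfinite(ge.Z).all()

    def test_all_head_counts_run(self):
        emb, gp, atil = self._blob_graph()
        for heads in (0, 1, 3):
            ge = train_gae(atil, emb, gp.adjacency, heads=heads, epochs=20, seed=1)
            assert np.isfinite(ge.loss_trace).all()
            assert ge.n_heads == heads

    def test_attention_rows_sum_to_one(self):
        emb, gp, atil = self._blob_graph()
        ge = train_gae(atil, emb, gp.adjacency, heads=2, epochs=10, seed=2)
        for layer in ge.attention:
            for att in layer:
                np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-8)


class TestClusterAE:
    def test_single_cluster_equals_feature_ae(self, rng):
        x = rng.random((20, 8))
        cfg = FeatureAEConfig(hidden_dim=8, latent_dim=4, epochs=50, alpha=0.0, seed=3)
        out = train_cluster_ae(x, np.zeros(20, int), cfg, min_cluster_size=5)
        cfg_same = FeatureAEConfig(
            hidden_dim=8, latent_dim=4, epochs=50, alpha=0.0, seed=cfg.seed + 1000
        )
        _, ref, _ = train_feature_ae(x, np.ones_like(x), cfg_same)
        np.testing.assert_allclose(out.values, ref.values)

    def test_reassembly_preserves_row_order(self, rng):
        x = rng.random((24, 6))
        labels = np.array([0, 1] * 12)
        cfg = FeatureAEConfig(hidden_dim=6, latent_dim=3, epochs=20, alpha=0.0, seed=0)
        out = train_cluster_ae(x, labels, cfg, min_cluster_size=5)
        # bookkeeping oracle: training each cluster separately and scattering
        for lab in (0, 1):
            idx = np.nonzero(labels == lab)[0]
            from scgraphae._nn import train_autoencoder

            _, _, rec, _ = train_autoencoder(
                x[idx], [6, 3], 1.0, cfg.learning_rate, 20, cfg.seed + 1000 + lab
            )
            np.testing.assert_allclose(out.values[idx], rec)

    def test_small_cluster_passed_through(self, rng):
        x = rng.random((12, 5))
        labels = np.array([0] * 10 + [1] * 2)
        cfg = FeatureAEConfig(hidden_dim=4, latent_dim=2, epochs=10, alpha=0.0, seed=0)
        out = train_cluster_ae(x, labels, cfg, min_cluster_size=5)
        np.testing.assert_array_equal(out.values[10:], x[10:])


class TestImputationLoss:
    def test_zero_when_perfect_and_no_l1(self, rng):
        x = rng.random((4, 3))
        b = np.eye(4)
        cfg = ImputationLossConfig(alpha=0.5, beta=0.0, gamma1=0.2, gamma2=0.2)
        assert imputation_loss(x, x, np.ones_like(x), np.zeros((4, 4)), b, cfg, 0.0) == 0.0

    def test_term_isolation(self, rng):
        x = rng.random((3, 2))
        xh = rng.random((3, 2))
        cfg = ImputationLossConfig(alpha=0.0, beta=1.0, gamma1=0.0, gamma2=0.0)
        got = imputation_loss(
            x, xh, np.zeros_like(x), np.zeros((3, 3)), np.eye(3) * 0, cfg, 2.5
        )
        assert got == pytest.approx(((x - xh) ** 2).sum() + 2.5, rel=1e-12)

    def test_five_term_oracle(self, rng):
        n, g = 4, 3
        x, xh = rng.random((n, g)), rng.random((n, g))
        w = rng.random((n, g))
        a = (rng.random((n, n)) < 0.5).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        labels = rng.integers(0, 2, n)
        b = (labels[:, None] == labels[None, :]).astype(float)
        cfg = ImputationLossConfig(alpha=0.3, beta=0.7, gamma1=0.2, gamma2=0.4)
        l1 = 1.7
        sq = (x - xh) ** 2
        row_err = sq.sum(1)
        oracle = (
            (1 - 0.3) * sq.sum()
            + 0.3 * (sq * w).sum()
            + 0.7 * l1
            + 0.2 * sum(a[i, j] * row_err[i] for i in range(n) for j in range(n))
            + 0.4 * sum(b[i, j] * row_err[i] for i in range(n) for j in range(n))
        )
        assert imputation_loss(x, xh, w, a, b, cfg, l1) == pytest.approx(oracle, rel=1e-12)

    def test_asymmetric_b_rejected(self, rng):
        x = rng.random((3, 2))
        bad = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            imputation_loss(
                x, x, np.ones_like(x), np.zeros((3, 3)), bad,
                ImputationLossConfig(), 0.0,
            )


class TestTrainImputationAE:
    def _setup(self, rng):
        u = np.abs(rng.normal(size=(30, 2)))
        v = np.abs(rng.normal(size=(2, 15)))
        x = u @ v
        labels = np.repeat([0, 1], 15)
        b = (labels[:, None] == labels[None, :]).astype(float)
        a = np.zeros((30, 30))
        return x, a, b

    def test_corruption_recovery(self, rng):
        x, a, b = self._setup(rng)
        corrupted = x.copy()
        nz = np.argwhere(x > 0)
        sel = nz[rng.choice(len(nz), size=len(nz) // 10, replace=False)]
        corrupted[sel[:, 0], sel[:, 1]] = 0.0
        cfg = FeatureAEConfig(hidden_dim=16, latent_dim=4, epochs=400, alpha=0.0, seed=0)
        loss_cfg = ImputationLossConfig(alpha=0.0, beta=0.0, gamma1=0.0, gamma2=0.05)
        rec, _ = train_imputation_ae(corrupted, a, b, np.ones_like(x), loss_cfg, cfg)
        truth = x[sel[:, 0], sel[:, 1]]
        imp = rec.values[sel[:, 0], sel[:, 1]]
        base = corrupted[sel[:, 0], sel[:, 1]]
        cos = lambda p, q: p @ q / (np.linalg.norm(p) * np.linalg.norm(q) + 1e-12)
        assert cos(truth, imp) > cos(truth, base)

    def test_l1_regularization_direction(self, rng):
        from scgraphae._nn import train_autoencoder

        x, _, _ = self._setup(rng)
        sums = {}
        for beta in (0.0, 1.0):
            model, _, _, _ = train_autoencoder(
                x, [8, 4], 1.0, lr=1e-3, epochs=150, seed=4, l1_beta=beta
            )
            sums[beta] = model.weight_l1()
        assert sums[1.0] < sums[0.0]

    def test_deterministic(self, rng):
        x, a, b = self._setup(rng)
        cfg = FeatureAEConfig(hidden_dim=8, latent_dim=4, epochs=30, alpha=0.0, seed=9)
        loss_cfg = ImputationLossConfig()
        r1, _ = train_imputation_ae(x, a, b, np.ones_like(x), loss_cfg, cfg)
        r2, _ = train_imputation_ae(x, a, b, np.ones_like(x), loss_cfg, cfg)
        np.testing.assert_array_equal(r1.values, r2.values)
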