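"""Structural and oracle tests for the six-stage connectivity network."""

import numpy as np
import pytest

import pairconn as pc
from pairconn.model import attention_weights, pearson_connectivity, reweight_embeddings


def _f_loop_oracle(net, emb):
    """Evaluate the similarity MLP pair-by-pair with plain numpy."""
    cfg = net.config
    N, d = emb.shape
    K = np.zeros((N, N))
    n_layers = len(cfg.similarity_hidden) + 1
    for i in range(N):
        for j in range(N):
            h = np.concatenate([emb[i], emb[j]])
            for li in range(n_layers):
                W = net.params[f"F.lin{li}.w"].data
                b = net.params[f"F.lin{li}.b"].data
                h = W @ h + b
                if li < n_layers - 1:
                    h = np.maximum(h, 0.0)
            K[i, j] = 1.0 / (1.0 + np.exp(-h[0]))
    return K


class TestEmbedding:
    def test_identical_series_get_identical_embeddings(self, tiny_model_config, tiny_batch):
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=0)
        x = tiny_batch.copy()
        x[:, 1] = x[:, 0]  # duplicate a region
        res = net.predict(x)
        np.testing.assert_allclose(res.embeddings[:, 0], res.embeddings[:, 1], atol=1e-12)

    def test_full_scale_geometry_117_regions_d32(self):
        """Full-width extractor maps a 117x300 scan to 117x32 embeddings
        and the classifier flattens 117^2 = 13689 entries into 100 features."""
        cfg = pc.ModelConfig(n_regions=117, n_timepoints=300)
        net = pc.PairwiseAttentionNet(cfg, seed=0)
        assert net.params["E.out.w"].data.shape[0] == 32
        assert net.params["C.lin0.w"].data.shape == (100, 117 ** 2)
        x = np.random.default_rng(0).normal(size=(1, 117, 300))
        from pairconn.autodiff import Tensor
        emb = net.embed(Tensor(x))
        assert emb.shape == (1, 117, 32)

    def test_identity_ablation_returns_raw_series(self, tiny_batch):
        cfg = pc.ModelConfig(n_regions=4, n_timepoints=16, identity_E=True,
                             head_size=3, similarity_hidden=(5, 4),
                             classifier_hidden=(100, 6), dropout=0.0)
        net = pc.PairwiseAttentionNet(cfg, seed=0)
        res = net.predict(tiny_batch)
        np.testing.assert_array_equal(res.embeddings, tiny_batch)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            pc.ModelConfig(n_regions=4, n_timepoints=8)


class TestPairwiseConnectivity:
    def test_constant_embeddings_give_constant_matrix(self, tiny_model_config):
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=1)
        x = np.ones((2, 4, 16))
        res = net.predict(x)
        assert np.ptp(res.K) < 1e-12

    def test_batched_equals_double_loop_oracle(self, tiny_model_config, tiny_batch):
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=2)
        res = net.predict(tiny_batch)
        for b in range(tiny_batch.shape[0]):
            expect = _f_loop_oracle(net, res.embeddings[b])
            np.testing.assert_allclose(res.K[b], expect, atol=1e-10)

    def test_entries_strictly_inside_unit_interval(self, tiny_model_config, tiny_batch):
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=3)
        res = net.predict(tiny_batch)
        for K in (res.K, res.K_prime):
            assert K.min() > 0.0 and K.max() < 1.0

    def test_pearson_ablation_matches_closed_form(self, tiny_batch):
        cfg = pc.ModelConfig(n_regions=4, n_timepoints=16, identity_E=True,
                             pearson_F=True, head_size=3,
                             classifier_hidden=(100, 6), dropout=0.0)
        net = pc.PairwiseAttentionNet(cfg, seed=0)
        res = net.predict(tiny_batch)
        for b in range(tiny_batch.shape[0]):
            x = tiny_batch[b]
            expect = np.zeros((4, 4))
            for i in range(4):
                for j in range(4):
                    xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                    expect[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            np.testing.assert_allclose(res.K[b], expect, atol=1e-10)


class TestAttention:
    def test_zero_matrix_gives_beta(self):
        w = attention_weights(np.zeros((5, 5)), beta=0.9)
        np.testing.assert_allclose(w, 0.9)

    def test_beta_one_gives_unit_weights(self):
        K = np.random.default_rng(0).uniform(size=(6, 6))
        np.testing.assert_allclose(attention_weights(K, 1.0), 1.0)

    def test_hand_computed_fixture(self):
        K = np.zeros((3, 3))
        K[0, 1], K[0, 2] = 0.5, 0.25          # row sums 0.75
        K[1, 0], K[1, 2] = 0.75, 0.75         # 1.5
        K[2, 0], K[2, 1] = 1.0, 0.25          # 1.25
        np.fill_diagonal(K, 0.77)             # diagonal must be ignored
        np.testing.assert_allclose(
            attention_weights(K, 0.9), [0.975, 1.05, 1.025], atol=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            attention_weights(np.zeros((3, 3)), 1.5)

    def test_weights_within_bounds_on_forward(self, tiny_model_config, tiny_batch):
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=4)
        res = net.predict(tiny_batch)
        beta, N = tiny_model_config.beta, 4
        assert res.weights.min() >= beta - 1e-9
        assert res.weights.max() <= beta + (1 - beta) * (N - 1) + 1e-9


class TestReweighting:
    def test_unit_weights_identity(self):
        emb = np.random.default_rng(1).normal(size=(4, 3))
        np.testing.assert_array_equal(reweight_embeddings(emb, np.ones(4)), emb)

    def test_row_scaling(self):
        emb = np.ones((2, 3))
        out = reweight_embeddings(emb, np.array([2.0, 0.0]))
        np.testing.assert_array_equal(out[0], 2.0)
        np.testing.assert_array_equal(out[1], 0.0)

    def test_updated_connectivity_equals_loop_oracle(self, tiny_model_config, tiny_batch):
        """k'_ij = F([w_i e_i, w_j e_j]) evaluated pairwise by hand."""
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=5)
        res = net.predict(tiny_batch)
        for b in range(tiny_batch.shape[0]):
            scaled = reweight_embeddings(res.embeddings[b], res.weights[b])
            np.testing.assert_allclose(res.K_prime[b], _f_loop_oracle(net, scaled),
                                       atol=1e-10)


class TestForward:
    def test_beta_one_makes_K_prime_equal_K(self, tiny_batch):
        cfg = pc.ModelConfig(n_regions=4, n_timepoints=16, embed_dim=3, beta=1.0,
                             head_size=3, conv_filters=(2, 3, 3, 4, 4, 4),
                             similarity_hidden=(5, 4), classifier_hidden=(100, 6),
                             dropout=0.0)
        net = pc.PairwiseAttentionNet(cfg, seed=6)
        res = net.predict(tiny_batch)
        np.testing.assert_allclose(res.K_prime, res.K, atol=1e-12)

    @pytest.mark.parametrize("l", [1, 3, 20])
    def test_head_sizes(self, l, tiny_batch):
        cfg = pc.ModelConfig(n_regions=4, n_timepoints=16, embed_dim=3, head_size=l,
                             conv_filters=(2, 3, 3, 4, 4, 4), similarity_hidden=(5, 4),
                             classifier_hidden=(100, 6), dropout=0.0)
        net = pc.PairwiseAttentionNet(cfg, seed=0)
        res = net.predict(tiny_batch)
        assert res.logits.shape == (3, l)
        assert res.hidden_features.shape == (3, 100)

    def test_no_reweighting_classifies_on_K(self, tiny_batch):
        cfg = pc.ModelConfig(n_regions=4, n_timepoints=16, embed_dim=3,
                             no_reweighting=True, head_size=3,
                             conv_filters=(2, 3, 3, 4, 4, 4), similarity_hidden=(5, 4),
                             classifier_hidden=(100, 6), dropout=0.0)
        net = pc.PairwiseAttentionNet(cfg, seed=0)
        res = net.predict(tiny_batch)
        assert res.K_prime is None and res.weights is None
        assert res.logits.shape == (3, 3)

    def test_region_permutation_covariance(self, tiny_model_config, tiny_batch):
        """Permuting region order permutes K, K' and w consistently."""
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=8)
        perm = np.array([2, 0, 3, 1])
        res = net.predict(tiny_batch)
        res_p = net.predict(tiny_batch[:, perm, :])
        np.testing.assert_allclose(res_p.K, res.K[:, perm][:, :, perm], atol=1e-10)
        np.testing.assert_allclose(res_p.weights, res.weights[:, perm], atol=1e-10)
        np.testing.assert_allclose(res_p.K_prime, res.K_prime[:, perm][:, :, perm],
                                   atol=1e-10)

    def test_state_dict_round_trip(self, tiny_model_config, tiny_batch):
        net = pc.PairwiseAttentionNet(tiny_model_config, seed=9)
        state = net.state_dict()
        net2 = pc.PairwiseAttentionNet(tiny_model_config, seed=123)
        net2.load_state_dict(state)
        np.testing.assert_array_equal(net.predict(tiny_batch).logits,
                                      net2.predict(tiny_batch).logits)


def test_pearson_connectivity_helper_against_numpy():
    x = np.random.default_rng(3).normal(size=(5, 11))
    np.testing.assert_allclose(pearson_connectivity(x), np.corrcoef(x), atol=1e-10)
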