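"""Layer oracles, forward-pass invariances, and gradient correctness."""

import numpy as np
import pytest

from ccgnet.graphdata import pad_batch
from ccgnet.network import (
    CCGNet,
    CCGNetConfig,
    GraphConvWeights,
    broadcast_concat,
    global_attention,
    global_state_update,
    graph_conv,
    masked_softmax,
    multihead_readout,
)
from ccgnet.synthetic import loop_graph_conv, tiny_graph_fixtures

identity = lambda x: x


class TestGraphConv:
    def test_two_node_hand_example(self):
        w = GraphConvWeights(h=np.ones((1, 1, 1)), W0=np.ones((1, 1)), b=np.zeros(1))
        out = graph_conv([[1.0], [2.0]], np.array([[0, 1], [1, 0.0]]).reshape(2, 2, 1),
                         w, activation=identity)
        assert np.array_equal(out, [[3.0], [3.0]])

    def test_zero_adjacency_identity_self_loop(self):
        V = np.arange(6, dtype=float).reshape(3, 2)
        w = GraphConvWeights(h=np.ones((2, 2, 2)), W0=np.eye(2), b=np.zeros(2))
        out = graph_conv(V, np.zeros((3, 3, 2)), w, activation=identity)
        assert np.allclose(out, V)

    def test_fixtures_match_expected(self):
        for fx in tiny_graph_fixtures():
            out = graph_conv(fx["V"], fx["A"], fx["weights"], activation=identity)
            assert np.allclose(out, fx["expected"]), fx["name"]

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            N = rng.integers(2, 7)
            L = rng.integers(1, 5)
            C = rng.integers(1, 6)
            F = rng.integers(1, 6)
            A = np.zeros((N, N, L))
            for _e in range(rng.integers(0, N * 2)):
                i, j = rng.integers(0, N, size=2)
                if i != j:
                    sl = rng.integers(0, L)
                    A[i, j, :] = 0
                    A[j, i, :] = 0
                    A[i, j, sl] = A[j, i, sl] = 1
            V = rng.normal(size=(N, C))
            w = GraphConvWeights(h=rng.normal(size=(L, C, F)),
                                 W0=rng.normal(size=(C, F)), b=rng.normal(size=F))
            fast = graph_conv(V, A, w, activation=identity)
            slow = loop_graph_conv(V, A, w)
            assert np.allclose(fast, slow, atol=1e-6)

    def test_shape_mismatch_raises(self):
        w = GraphConvWeights(h=np.ones((1, 3, 2)), W0=np.ones((3, 2)), b=np.zeros(2))
        with pytest.raises(ValueError, match="shape"):
            graph_conv(np.ones((2, 2)), np.zeros((2, 2, 1)), w)


class TestGlobalState:
    def test_identity(self):
        u = np.random.default_rng(0).normal(size=(2, 4))
        assert np.allclose(global_state_update(u, np.eye(4), np.zeros(4), identity), u)

    def test_zero_weight_relu_bias(self):
        u = np.random.default_rng(0).normal(size=(2, 3))
        c = np.array([1.5, -2.0, 0.0])
        out = global_state_update(u, np.zeros((3, 3)), c)
        assert np.allclose(out, np.maximum(c, 0)[None, :].repeat(2, axis=0))

    def test_matches_affine_oracle(self):
        rng = np.random.default_rng(5)
        u, W, b = rng.normal(size=(2, 6)), rng.normal(size=(6, 4)), rng.normal(size=4)
        assert np.allclose(global_state_update(u, W, b, identity), u @ W + b, atol=1e-12)


class TestBroadcastConcat:
    def test_width_and_per_coformer_rows(self):
        V = np.zeros((5, 3))
        u = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = broadcast_concat(V, u, (slice(0, 2), slice(2, 5)))
        assert out.shape == (5, 5)
        assert np.array_equal(out[0, 3:], out[1, 3:])
        assert np.array_equal(out[0, 3:], [1, 2])
        assert np.array_equal(out[3, 3:], [3, 4])

    def test_swap_equals_row_permutation(self):
        rng = np.random.default_rng(1)
        V = rng.normal(size=(5, 3))
        u = rng.normal(size=(2, 2))
        fwd = broadcast_concat(V, u, (slice(0, 2), slice(2, 5)))
        perm = np.r_[2:5, 0:2]
        swapped = broadcast_concat(V[perm], u[::-1], (slice(0, 3), slice(3, 5)))
        assert np.allclose(swapped, fwd[perm])

    def test_bad_slices_raise(self):
        with pytest.raises(ValueError, match="partition"):
            broadcast_concat(np.zeros((4, 2)), np.zeros((2, 2)),
                             (slice(0, 2), slice(3, 4)))


class TestAttention:
    def test_constant_scorer_gives_mean(self):
        V = np.random.default_rng(2).normal(size=(5, 3))
        x, alpha = global_attention(V, lambda v: np.zeros(len(v)))
        assert np.allclose(alpha, 0.2)
        assert np.allclose(x, V.mean(axis=0))

    def test_hand_computed_softmax(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        x, alpha = global_attention(V, lambda v: np.array([0.0, np.log(3.0)]))
        assert np.allclose(alpha, [0.25, 0.75])
        assert np.allclose(x, [0.25, 0.75])

    def test_padded_node_ignored(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(4, 3))
        Vp = np.vstack([V, np.zeros(3)])
        phi = lambda v: v @ np.array([1.0, -0.5, 2.0])
        x, _ = global_attention(V, phi)
        xp, alpha_p = global_attention(Vp, phi, mask=np.array([1, 1, 1, 1, 0.0]))
        assert np.allclose(x, xp)
        assert alpha_p[-1] == 0

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="masked"):
            masked_softmax(np.zeros(3), np.zeros(3))

    def test_multihead_single_head_equals_global(self):
        rng = np.random.default_rng(4)
        V = rng.normal(size=(6, 4))
        phi = (rng.normal(size=(4, 3)), rng.normal(size=3),
               rng.normal(size=3), np.zeros(1))
        x1, _ = global_attention(V, phi)
        xc, alpha = multihead_readout(V, [phi])
        assert np.allclose(xc, x1)
        assert alpha.shape == (6, 1)

    def test_multihead_width_and_identical_heads(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(5, 8))
        phi = (rng.normal(size=(8, 3)), rng.normal(size=3),
               rng.normal(size=3), np.zeros(1))
        xc, _ = multihead_readout(V, [phi, phi, phi])
        assert xc.shape == (24,)
        assert np.allclose(xc[:8], xc[8:16]) and np.allclose(xc[:8], xc[16:])


class TestFullModel:
    def test_decision_rule_and_tie_break(self):
        from ccgnet.network import CCGNet

        logits = np.array([[0.2, 0.9], [0.9, 0.2], [0.5, 0.5]])
        labels = (logits[:, 1] > logits[:, 0]).astype(int)
        assert list(labels) == [1, 0, 0]  # tie classifies negative

    def test_block_widths_follow_config(self, tiny_model):
        model, batch = tiny_model
        cfg = model.config
        assert model.node_width == cfg.conv_widths[-1] + cfg.global_widths[-1]
        logits = model.forward(batch)
        assert logits.shape == (batch["mask"].shape[0], 2)

    def test_padding_invariance(self, sample_pair, tiny_model):
        model, _ = tiny_model
        p1 = model.forward(pad_batch([sample_pair], n_max=25))
        p2 = model.forward(pad_batch([sample_pair], n_max=64))
        assert np.allclose(p1, p2, atol=1e-6)

    def test_within_coformer_node_permutation_invariance(self, sample_pair, tiny_model):
        import dataclasses

        model, _ = tiny_model
        n1 = sample_pair.coformer_slices[0].stop
        rng = np.random.default_rng(0)
        perm = np.concatenate([rng.permutation(n1),
                               n1 + rng.permutation(sample_pair.num_nodes - n1)])
        permuted = dataclasses.replace(
            sample_pair, V=sample_pair.V[perm], A=sample_pair.A[np.ix_(perm, perm)])
        a = model.forward(pad_batch([sample_pair], n_max=40))
        b = model.forward(pad_batch([permuted], n_max=40))
        assert np.allclose(a, b, atol=1e-8)

    @pytest.mark.parametrize("mode,simple", [("MG", False), ("MG+2D", False),
                                             ("MG+3D", False), ("MG+2D+3D", True)])
    def test_feature_modes_and_simple_variant_run(self, sample_pairs, mode, simple):
        batch = pad_batch(sample_pairs, n_max=40)
        model = CCGNet(CCGNetConfig(conv_widths=(4, 4), global_widths=(3, 3),
                                    attention_heads=1, attention_hidden=3,
                                    dense_head=(5, 2), feature_mode=mode, simple=simple))
        model.fit_scalers(batch)
        loss, grads = model.loss_and_grads(batch)
        assert np.isfinite(loss)
        assert all(np.all(np.isfinite(g)) for g in grads.values())

    def test_default_depth_is_four_blocks(self):
        assert len(CCGNetConfig().conv_widths) == 4

    def test_gradients_match_finite_differences(self, tiny_model):
        model, batch = tiny_model
        _, grads = model.loss_and_grads(batch)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name, tensor in model.params.items():
            flat = tensor.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = model.loss(batch)
                flat[i] = orig - eps
                lm = model.loss(batch)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert abs(num - ana) < 1e-6 * (1 + abs(num)), name

    def test_attention_map_normalized_per_head(self, sample_pairs, tiny_model):
        model, _ = tiny_model
        batch = pad_batch(sample_pairs, n_max=40)
        maps = model.attention_map(batch)
        assert len(maps) == len(sample_pairs)
        for g, w in zip(sample_pairs, maps):
            assert w.shape == (g.num_nodes, model.config.attention_heads)
            assert np.all(w >= 0)
            assert np.allclose(w.sum(axis=0), 1.0, atol=1e-6)

    def test_state_round_trip_preserves_predictions(self, sample_pairs, tiny_model):
        model, _ = tiny_model
        batch = pad_batch(sample_pairs, n_max=40)
        clone = CCGNet.from_state(model.state())
        assert np.array_equal(model.forward(batch), clone.forward(batch))
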