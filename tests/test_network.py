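"""Architecture-level behaviour: GRU recurrences, attention, conv blocks,
pooling, the classifier head, ablation wiring and checkpointing."""

import numpy as np
import pytest

from ac4cnet import NetworkConfig, RnaRecord, integer_encode, positional_encoding
from ac4cnet.autograd import Tensor, embedding as embed_lookup
from ac4cnet.network import (
    BiGRU,
    Classifier,
    ConvBlock,
    DualPathClassifier,
    GRUCell,
    MultiHeadAttention,
    pool_path,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestEmbedding:
    def test_zero_table_leaves_positional_encoding(self):
        table = Tensor(np.zeros((4, 8)))
        codes = integer_encode("ACGUA")
        out = embed_lookup(table, codes).data + positional_encoding(5, 8)
        assert np.array_equal(out, positional_encoding(5, 8))

    def test_lookup_locality(self):
        rng = np.random.default_rng(0)
        table = Tensor(rng.normal(size=(4, 6)))
        a = embed_lookup(table, integer_encode("AAGAA")).data
        b = embed_lookup(table, integer_encode("AACAA")).data
        diff_rows = np.flatnonzero(np.any(a != b, axis=1))
        assert diff_rows.tolist() == [2]


class TestGru:
    def test_zero_parameters_fixed_point(self):
        rng = np.random.default_rng(1)
        cell = GRUCell(rng, d_in=3, hidden=4)
        for t in cell.parameters():
            t.data[...] = 0.0
        X = Tensor(np.random.default_rng(2).normal(size=(2, 5, 3)))
        states = cell.run(X)
        assert all(np.array_equal(h.data, np.zeros((2, 4))) for h in states)

    def test_scalar_one_step_hand_computed(self):
        # 1-d input, 1-d hidden, one step from h0 = 0 with hand-set weights.
        rng = np.random.default_rng(3)
        cell = GRUCell(rng, d_in=1, hidden=1)
        vals = dict(W_zx=0.5, W_zh=0.2, b_zx=0.1, b_zh=-0.3,
                    W_rx=-0.4, W_rh=0.6, b_rx=0.2, b_rh=0.0,
                    W_hx=0.7, W_hh=-0.5, b_hx=0.05, b_hh=0.15)
        for name, v in vals.items():
            getattr(cell, name).data[...] = v
        x = 0.8
        h = cell.step(Tensor(np.array([[x]])), Tensor(np.zeros((1, 1)))).data[0, 0]
        z = _sigmoid(vals["W_zx"] * x + vals["b_zx"] + vals["b_zh"])
        r = _sigmoid(vals["W_rx"] * x + vals["b_rx"] + vals["b_rh"])
        cand = np.tanh(vals["W_hx"] * x + vals["b_hx"] + r * vals["b_hh"])
        assert h == pytest.approx(z * cand, abs=1e-10)

    def test_backward_half_equals_reversed_forward_oracle(self):
        # Oracle: running the *forward* recurrence on the reversed sequence
        # and reversing the states must reproduce the backward half.
        rng = np.random.default_rng(4)
        gru = BiGRU(rng, d_in=3, hidden=5, bidirectional=True)
        for (name, p_b) in gru.bwd.named_parameters().items():
            p_b.data[...] = gru.fwd.named_parameters()[name].data
        X = np.random.default_rng(5).normal(size=(2, 7, 3))
        out = gru(Tensor(X)).data  # (2, 7, 10)
        rev_states = gru.fwd.run(Tensor(X[:, ::-1, :]))
        oracle = np.stack([h.data for h in rev_states], axis=1)[:, ::-1, :]
        assert np.allclose(out[:, :, 5:], oracle, atol=1e-12)

    def test_sigmoid_at_zero(self):
        assert float(Tensor(np.array(0.0)).sigmoid().data) == 0.5


class TestConvBlock:
    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(6)
        block = ConvBlock(rng, 1, 3, kernel=3, padding=1, pool_width=2)
        block.b.data[...] = 0.0
        out = block(Tensor(np.zeros((2, 1, 8))))
        assert np.array_equal(out.data, np.zeros_like(out.data))

    def test_outputs_nonnegative(self):
        rng = np.random.default_rng(7)
        block = ConvBlock(rng, 2, 4, kernel=4, padding=2, pool_width=2)
        out = block(Tensor(np.random.default_rng(8).normal(size=(3, 2, 10))))
        assert np.all(out.data >= 0.0)

    def test_matches_sliding_dot_product_oracle(self):
        rng = np.random.default_rng(9)
        block = ConvBlock(rng, 1, 1, kernel=3, padding=0, pool_width=2)
        x = np.random.default_rng(10).normal(size=(1, 1, 8))
        out = block(Tensor(x)).data[0, 0]
        w = block.W.data[0, 0]
        b = float(block.b.data[0])
        conv = np.array([x[0, 0, i : i + 3] @ w + b for i in range(6)])
        oracle = np.maximum(conv, 0.0).reshape(3, 2).max(axis=1)
        assert np.allclose(out, oracle, atol=1e-12)

    def test_kernel_exceeding_length_rejected(self):
        rng = np.random.default_rng(11)
        block = ConvBlock(rng, 1, 1, kernel=9, padding=0, pool_width=2)
        with pytest.raises(ValueError, match="kernel"):
            block(Tensor(np.zeros((1, 1, 4))))


class TestAttention:
    def test_single_row_degenerates_to_value_projection(self):
        rng = np.random.default_rng(12)
        attn = MultiHeadAttention(rng, d_model=8, heads=2)
        x = np.random.default_rng(13).normal(size=(1, 1, 8))
        out = attn(Tensor(x)).data
        expected = (x @ attn.W_V.data) @ attn.W_o.data
        assert np.allclose(out, expected, atol=1e-12)

    def test_identical_rows_give_identical_outputs(self):
        rng = np.random.default_rng(14)
        attn = MultiHeadAttention(rng, d_model=8, heads=4)
        row = np.random.default_rng(15).normal(size=8)
        out = attn(Tensor(np.tile(row, (1, 5, 1)))).data[0]
        assert np.allclose(out, out[0], atol=1e-12)

    def test_two_row_single_head_hand_computed(self):
        rng = np.random.default_rng(16)
        d = 4
        attn = MultiHeadAttention(rng, d_model=d, heads=1)
        x = np.random.default_rng(17).normal(size=(1, 2, d))
        out = attn(Tensor(x)).data[0]
        Q, K, V = x[0] @ attn.W_Q.data, x[0] @ attn.W_K.data, x[0] @ attn.W_V.data
        scores = Q @ K.T / np.sqrt(d)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        weights = e / e.sum(axis=1, keepdims=True)
        oracle = (weights @ V) @ attn.W_o.data
        assert np.allclose(out, oracle, atol=1e-10)

    def test_row_softmax_weights_sum_to_one(self):
        rng = np.random.default_rng(18)
        attn = MultiHeadAttention(rng, d_model=8, heads=2)
        _, weights = attn(Tensor(np.random.default_rng(19).normal(size=(2, 6, 8))),
                          return_weights=True)
        assert np.allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(20)
        attn = MultiHeadAttention(rng, d_model=8, heads=2)
        x = np.random.default_rng(21).normal(size=(1, 5, 8))
        perm = np.array([3, 0, 4, 1, 2])
        out = attn(Tensor(x)).data[0]
        out_perm = attn(Tensor(x[:, perm, :])).data[0]
        assert np.allclose(out_perm, out[perm], atol=1e-10)


class TestPoolAndClassifier:
    def test_pool_modes(self):
        x = Tensor(np.arange(12.0).reshape(1, 3, 4))
        assert np.allclose(pool_path(x, "mean").data, x.data.mean(axis=1))
        assert np.allclose(pool_path(x, "max").data, x.data.max(axis=1))
        assert pool_path(x, "flatten").data.shape == (1, 12)
        single = Tensor(np.arange(4.0).reshape(1, 1, 4))
        assert np.array_equal(pool_path(single, "mean").data[0], single.data[0, 0])

    def test_equal_logits_give_half_half(self):
        rng = np.random.default_rng(22)
        clf = Classifier(rng, d_in=4, hidden=3, dropout=0.0)
        clf.lin1.W.data[...] = 0.0
        clf.lin1.b.data[...] = 0.0
        clf.lin2.W.data[...] = 0.0
        clf.lin2.b.data[...] = 0.0
        probs = clf(Tensor(np.random.default_rng(23).normal(size=(5, 4)))).data
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(24)
        clf = Classifier(rng, d_in=4, hidden=3, dropout=0.0)
        probs = clf(Tensor(np.random.default_rng(25).normal(size=(7, 4)))).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0.0)

    def test_zero_hidden_path_reduces_to_softmax_of_bias(self):
        rng = np.random.default_rng(26)
        clf = Classifier(rng, d_in=4, hidden=3, dropout=0.0)
        clf.lin1.W.data[...] = 0.0
        clf.lin1.b.data[...] = 0.0
        clf.lin2.W.data[...] = 0.0
        clf.lin2.b.data[...] = np.array([1.0, -1.0])
        probs = clf(Tensor(np.zeros((1, 4)))).data[0]
        e = np.exp([1.0, -1.0])
        assert np.allclose(probs, e / e.sum(), atol=1e-12)


class TestFullModel:
    def test_default_config_head_width(self):
        cfg = NetworkConfig()
        assert cfg.d_model == 512 and cfg.heads == 8 and cfg.d_k == 64

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(d_model=10, heads=4)

    def test_eval_forward_is_deterministic(self, tiny_model, tiny_records):
        p1 = tiny_model.predict_proba(tiny_records[:4])
        p2 = tiny_model.predict_proba(tiny_records[:4])
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0.0) & (p1 <= 1.0))

    @pytest.mark.parametrize("overrides", [
        {"use_path2": False},
        {"use_path1": False},
        {"use_positional_encoding": False},
        {"use_attention": False},
        {"use_path2": False, "feature_scheme": "onehot"},
    ])
    def test_ablated_variants_emit_valid_probabilities(self, tiny_config,
                                                       tiny_records, overrides):
        model = DualPathClassifier(tiny_config.ablate(**overrides), seed=1)
        probs = model.predict_proba(tiny_records[:4])
        assert probs.shape == (4,)
        assert np.all((probs >= 0.0) & (probs <= 1.0))

    def test_parameter_inventory_tracks_ablation(self, tiny_config):
        full = DualPathClassifier(tiny_config, seed=0)
        path1 = DualPathClassifier(tiny_config.ablate(use_path2=False), seed=0)
        path2 = DualPathClassifier(tiny_config.ablate(use_path1=False), seed=0)
        assert any("conv" in n for n in full.named_parameters())
        assert not any("conv" in n for n in path1.named_parameters())
        assert not any(n.startswith(("embedding", "gru", "attn1", "bridge1"))
                       for n in path2.named_parameters())

    def test_parameter_count_is_function_of_config(self, tiny_config):
        a = DualPathClassifier(tiny_config, seed=0).parameter_count()
        b = DualPathClassifier(tiny_config, seed=99).parameter_count()
        assert a == b
        smaller = DualPathClassifier(tiny_config.ablate(use_path2=False),
                                     seed=0).parameter_count()
        assert smaller < a

    def test_checkpoint_roundtrip(self, tmp_path, trained_tiny):
        model, val, _ = trained_tiny
        path = tmp_path / "ckpt.npz"
        model.save(path, metadata={"note": "unit test"})
        clone = model.load(path)
        assert np.allclose(clone.predict_proba(val), model.predict_proba(val),
                           atol=0.0)
        assert clone.config == model.config
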