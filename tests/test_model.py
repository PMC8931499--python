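"""Attention arithmetic, layer contracts, loss closed forms, gradient
correctness and training behavior of the stacked self-attention classifier."""

import numpy as np
import pytest

import meghfo as m
from meghfo.model import (
    ModelConfig,
    TrainConfig,
    TransformerDetector,
    cross_entropy_loss,
    dense_pool,
    frame_tokens,
    multi_head_attention,
    scaled_attention,
)
from meghfo.nn import EncoderLayer, LayerNorm, softmax


def loop_multi_head(X, Wq, Wk, Wv, Wo, scale="sqrt"):
    """Per-head loop oracle for the batched implementation."""
    heads = []
    for i in range(Wq.shape[0]):
        Q, K, V = X @ Wq[i], X @ Wk[i], X @ Wv[i]
        dk = Q.shape[-1]
        c = dk ** -0.5 if scale == "sqrt" else 1.0 / dk
        S = Q @ K.T * c
        E = np.exp(S - S.max(axis=1, keepdims=True))
        A = E / E.sum(axis=1, keepdims=True)
        heads.append(A @ V)
    return np.concatenate(heads, axis=1) @ Wo


class TestScaledAttention:
    def test_single_token_returns_value(self, rng):
        Q = rng.normal(size=(1, 4))
        K = rng.normal(size=(1, 4))
        V = rng.normal(size=(1, 6))
        np.testing.assert_allclose(scaled_attention(Q, K, V), V, atol=1e-12)

    def test_zero_query_averages_values(self, rng):
        K = rng.normal(size=(5, 3))
        V = rng.normal(size=(5, 2))
        out = scaled_attention(np.zeros((4, 3)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)),
                                   atol=1e-12)

    def test_identity_2x2_closed_form(self):
        """Hand-computed: scores I/sqrt(2), softmax([0.7071, 0])."""
        I = np.eye(2)
        out = scaled_attention(I, I, I)
        e = np.exp(1 / np.sqrt(2))
        p = e / (e + 1)
        np.testing.assert_allclose(out[0], [p, 1 - p], atol=1e-4)
        np.testing.assert_allclose(out[0], [0.6698, 0.3302], atol=1e-4)

    def test_rows_are_probability_weights(self, rng):
        Q = rng.normal(size=(7, 5))
        A = softmax(Q @ Q.T / np.sqrt(5), axis=-1)
        assert np.all(A >= 0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))


class TestMultiHead:
    def test_single_head_identity_reduces_to_attention(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        I = np.eye(4)[None]
        out = multi_head_attention(X, I, I, I, np.eye(4))
        np.testing.assert_allclose(out, scaled_attention(X, X, X), atol=1e-12)

    @pytest.mark.parametrize("h", [1, 2, 4])
    def test_output_shape(self, h, rng):
        n, d = 5, 8
        dk = d // h
        X = rng.normal(size=(n, d))
        Wq = rng.normal(size=(h, d, dk))
        Wk = rng.normal(size=(h, d, dk))
        Wv = rng.normal(size=(h, d, dk))
        Wo = rng.normal(size=(h * dk, d))
        assert multi_head_attention(X, Wq, Wk, Wv, Wo).shape == (n, d)

    def test_batched_layer_matches_loop_oracle(self, rng):
        """The vectorized multi-head layer equals an explicit per-head loop."""
        d, h = 8, 2
        layer = __import__("meghfo.nn", fromlist=["MultiHeadSelfAttention"])\
            .MultiHeadSelfAttention(d, h, rng, dtype=np.float64)
        for _ in range(20):
            X = rng.normal(size=(1, 6, d))
            got = layer.forward(X)
            want = loop_multi_head(X[0], layer.params["Wq"], layer.params["Wk"],
                                   layer.params["Wv"], layer.params["Wo"]) \
                + layer.params["bo"]
            np.testing.assert_allclose(got[0], want, atol=1e-6)


class TestFraming:
    def test_reshape_arithmetic(self, rng):
        x = rng.normal(size=2000)
        F = frame_tokens(x, 20)
        assert F.shape == (100, 20)
        np.testing.assert_array_equal(F[3], x[60:80])
        np.testing.assert_array_equal(F.reshape(-1), x)

    def test_invalid_width_lists_alternatives(self):
        with pytest.raises(ValueError, match="valid widths"):
            frame_tokens(np.zeros(2000), 23)


class TestLayer:
    def test_layernorm_row_statistics(self, rng):
        d = 16
        ln = LayerNorm(d, dtype=np.float64)
        ln.params["gamma"] = rng.normal(size=d)  # affine must not matter
        ln.forward(rng.normal(2.0, 3.0, size=(4, 5, d)))
        pre = ln.last_normalized
        assert np.max(np.abs(pre.mean(axis=-1))) < 1e-6
        assert np.max(np.abs(pre.var(axis=-1) - 1)) < 1e-4

    def test_zeroed_sublayer_isolates_residual_path(self, rng):
        """With all sublayer weights zero, the block is Norm(ReLU(x))."""
        d = 8
        layer = EncoderLayer(d, 2, 16, rng, dtype=np.float64)
        for block in (layer.block1, layer.block2):
            for k in block.sub.named_params():
                block.sub.named_params()[k][...] = 0.0
        X = rng.normal(size=(2, 5, d))
        got = layer.forward(X)
        ref = X
        for block in (layer.block1, layer.block2):
            z = np.maximum(ref, 0.0)
            mu = z.mean(axis=-1, keepdims=True)
            sd = np.sqrt(z.var(axis=-1, keepdims=True) + 1e-5)
            ref = (z - mu) / sd
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_stack_is_sequential_composition(self, rng):
        d = 8
        layers = [EncoderLayer(d, 2, 16, rng, dtype=np.float64) for _ in range(3)]
        X = rng.normal(size=(1, 4, d))
        seq = X
        for l in layers:
            seq = l.forward(seq)
        chain = layers[2].forward(layers[1].forward(layers[0].forward(X)))
        np.testing.assert_allclose(seq, chain, atol=1e-12)


class TestDensePool:
    def test_zero_weights_return_bias(self):
        assert dense_pool(np.ones(3), np.zeros((4, 3)), np.zeros(4),
                          np.zeros(4), 2.5) == 2.5

    def test_hand_arithmetic(self):
        s = np.array([1.0, -1.0])
        out = dense_pool(s, np.eye(2), np.zeros(2), np.array([2.0, 3.0]), 1.0)
        assert out == pytest.approx(3.0)

    def test_negative_preactivations_contribute_zero(self):
        s = np.array([-5.0, -1.0])
        out = dense_pool(s, np.eye(2), np.zeros(2), np.array([7.0, 7.0]), 0.0)
        assert out == 0.0


class TestLoss:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy_loss([1.0], [1.0]) == pytest.approx(0.0, abs=2e-7)

    def test_half_probability_is_ln2(self):
        assert cross_entropy_loss([1.0], [0.5]) == pytest.approx(np.log(2), rel=1e-9)

    def test_clipping_keeps_loss_finite(self):
        assert cross_entropy_loss([1.0], [0.0]) == pytest.approx(-np.log(1e-7))

    def test_matches_brute_force_sum(self, rng):
        y = rng.integers(0, 2, 50).astype(float)
        p = rng.uniform(0.01, 0.99, 50)
        brute = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                          for yi, pi in zip(y, p)])
        assert cross_entropy_loss(y, p) == pytest.approx(brute, abs=1e-6)


class TestDetector:
    def _tiny(self, tiny_config, seed=0, **tkw):
        return TransformerDetector(tiny_config, TrainConfig(seed=seed, **tkw),
                                   dtype=np.float64)

    def test_forward_probability_range_and_determinism(self, tiny_config, rng):
        det = self._tiny(tiny_config).build(40)
        x = rng.normal(size=40)
        p1, p2 = det.forward(x), det.forward(x)
        assert 0 < p1 < 1
        assert p1 == p2

    def test_zeroed_output_layer_gives_half(self, tiny_config, rng):
        det = self._tiny(tiny_config).build(40)
        out = det.head[-1]
        out.params["W"][...] = 0
        out.params["b"][...] = 0
        assert det.forward(rng.normal(size=40)) == pytest.approx(0.5)

    def test_gradients_match_finite_differences(self, tiny_config, rng):
        """Backprop agrees with central differences through the full stack."""
        det = self._tiny(tiny_config).build(40)
        X = rng.normal(size=(3, 40)).astype(np.float64)
        y = np.array([1.0, 0.0, 1.0])

        def loss_value():
            from scipy.special import expit
            return cross_entropy_loss(y, expit(det._logits(X)))

        from scipy.special import expit
        p = expit(det._logits(X, train=True))
        det._backward((p - y) / len(y))
        checked = 0
        for mod in det._modules():
            for name, arr in mod.named_params().items():
                layer = mod
                key = name.split(".")[-1]
                # find owning leaf
                parts = name.split(".")[:-1]
                for part in parts:
                    layer = dict(layer.children())[part]
                g = layer.grads[key]
                flat_idx = rng.integers(0, arr.size, size=min(3, arr.size))
                for fi in flat_idx:
                    orig = arr.flat[fi]
                    eps = 1e-5
                    arr.flat[fi] = orig + eps
                    lp = loss_value()
                    arr.flat[fi] = orig - eps
                    lm = loss_value()
                    arr.flat[fi] = orig
                    num = (lp - lm) / (2 * eps)
                    assert g.flat[fi] == pytest.approx(num, abs=2e-5), name
                    checked += 1
        assert checked > 30

    def test_training_history_and_determinism(self, small_dataset, tiny_config):
        det1 = self._tiny(tiny_config, seed=5)
        det2 = self._tiny(tiny_config, seed=5)
        X = small_dataset.X[:, :400]
        y = small_dataset.y
        det1.fit(X, y)
        det2.fit(X, y)
        assert len(det1.history_) == 10
        assert det1.history_ == det2.history_
        np.testing.assert_array_equal(det1.predict(X), det2.predict(X))

    def test_loss_decreases_on_separable_data(self, small_dataset, tiny_config):
        for seed in range(3):
            cfg = ModelConfig(n_layers=1, n_heads=2, d_model=16, frame_width=20,
                              ffn_width=32)
            det = TransformerDetector(cfg, TrainConfig(seed=seed))
            det.fit(small_dataset.X, small_dataset.y)
            assert det.history_[-1] < det.history_[0]

    def test_single_class_data_rejected(self, tiny_config):
        det = self._tiny(tiny_config)
        with pytest.raises(ValueError):
            det.fit(np.zeros((4, 40)), np.array([m.HFO] * 4))

    def test_wrong_length_rejected(self, tiny_config, rng):
        det = self._tiny(tiny_config).build(40)
        with pytest.raises(ValueError):
            det.predict_proba(rng.normal(size=(2, 50)))

    def test_predict_threshold_and_cardinality(self, tiny_config, rng):
        det = self._tiny(tiny_config).build(40)
        X = rng.normal(size=(5, 40))
        labels, probs = m.predict(det, X, threshold=0.5)
        assert labels.shape == probs.shape == (5,)
        np.testing.assert_array_equal(labels, (probs >= 0.5).astype(int))
        empty_l, empty_p = m.predict(det, np.empty((0, 40)))
        assert empty_l.size == 0 and empty_p.size == 0

    def test_save_load_roundtrip(self, tiny_config, tmp_path, rng):
        det = self._tiny(tiny_config).build(40)
        x = rng.normal(size=(3, 40))
        det.save(tmp_path / "model")
        loaded = TransformerDetector.load(tmp_path / "model")
        np.testing.assert_allclose(loaded.predict_proba(x.astype(np.float32)),
                                   det.predict_proba(x), atol=1e-5)

    def test_end_to_end_holdout_accuracy(self):
        """Default config, two stacked layers, strong-SNR synthetic segments."""
        ds = m.preprocess_dataset(m.simulate_dataset(60, 60, seed=77))
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(ds))
        tr, te = idx[:80], idx[80:]
        det = TransformerDetector(ModelConfig(n_layers=2), TrainConfig(seed=0))
        det.fit(ds.X[tr], ds.y[tr])
        acc = np.mean(det.predict(ds.X[te]) == (ds.y[te] == m.HFO))
        assert acc >= 0.9
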