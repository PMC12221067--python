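import numpy as np
import pytest

from fasf_tle.autodiff import Tensor, stack
from fasf_tle.haetn import (
    CBAM,
    Dense,
    DepthwiseSeparableConv2D,
    HAETNClassifier,
    MultiHeadAttention,
    TemporalAttention,
    TransformerBlock,
    bilstm_attention,
    gradcam_map,
    max_pool_2x2,
    positional_encoding,
)
from tests.conftest import DESK_HAETN


class TestSeparableConv:
    def test_identity_kernel_passes_input_through(self):
        rng = np.random.default_rng(0)
        conv = DepthwiseSeparableConv2D(rng, 1, 1, kernel=3)
        conv.depth.data[:] = 0.0
        conv.depth.data[1, 1, 0] = 1.0
        conv.point.data[:] = 1.0
        conv.bias.data[:] = 0.0
        x = rng.random((1, 5, 5, 1))
        out = conv(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_all_ones_kernel_sums_neighbourhood(self):
        rng = np.random.default_rng(0)
        conv = DepthwiseSeparableConv2D(rng, 1, 1, kernel=3)
        conv.depth.data[:] = 1.0
        conv.point.data[:] = 1.0
        conv.bias.data[:] = 0.0
        x = np.arange(9, dtype=float).reshape(1, 3, 3, 1)
        out = conv(Tensor(x))
        assert out.data[0, 1, 1, 0] == x.sum()

    def test_parameter_count_smaller_than_full_conv(self):
        rng = np.random.default_rng(0)
        K, L, k = 8, 16, 3
        conv = DepthwiseSeparableConv2D(rng, K, L, k)
        assert conv.n_parameters == K * k**2 + K * L + L
        assert K * k**2 + K * L < K * L * k**2


class TestCBAM:
    def test_attention_maps_bounded(self):
        rng = np.random.default_rng(1)
        cbam = CBAM(rng, 4)
        x = Tensor(rng.normal(size=(2, 6, 6, 4)))
        mc = cbam.channel_attention(x).data
        ms = cbam.spatial_attention(x).data
        assert np.all((mc > 0) & (mc < 1))
        assert np.all((ms > 0) & (ms < 1))

    def test_output_attenuates_input(self):
        rng = np.random.default_rng(2)
        cbam = CBAM(rng, 3)
        x = rng.normal(size=(1, 4, 4, 3))
        out = cbam(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_zero_weights_give_quarter_passthrough(self):
        rng = np.random.default_rng(3)
        cbam = CBAM(rng, 2)
        for p in cbam.params():
            p.data[:] = 0.0
        x = rng.normal(size=(1, 4, 4, 2))
        out = cbam(Tensor(x)).data
        np.testing.assert_allclose(out, 0.25 * x, atol=1e-12)


class TestSequenceLayers:
    def test_bilstm_attention_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        v, alpha = bilstm_attention(rng.normal(size=(5, 3)), hidden=4)
        assert abs(alpha.sum() - 1.0) <= 1e-6
        assert v.shape == (8,)

    def test_single_timestep_gets_full_weight(self):
        v, alpha = bilstm_attention(np.ones((1, 3)), hidden=4)
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_hidden_states_get_uniform_weights(self):
        # symmetry of the attention layer itself: identical h_t must
        # receive identical weights (the recurrent states feeding it in
        # the full model legitimately differ across time)
        rng = np.random.default_rng(8)
        attn = TemporalAttention(rng, 6)
        h = Tensor(np.tile(rng.normal(size=(1, 1, 6)), (1, 5, 1)))
        _, alpha = attn(h)
        np.testing.assert_allclose(alpha.data, np.full((1, 5), 0.2), atol=1e-9)

    def test_positional_encoding_values(self):
        pe = positional_encoding(10, 8)
        assert np.all(pe[0, 0::2] == 0.0) and np.all(pe[0, 1::2] == 1.0)
        assert pe.min() >= -1.0 and pe.max() <= 1.0
        assert pe[1, 0] == pytest.approx(np.sin(1.0))

    def test_positional_encoding_needs_even_width(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding(4, 7)


class TestAttentionAndTransformer:
    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        mha = MultiHeadAttention(rng, 8, 2)
        x = Tensor(rng.normal(size=(2, 5, 8)))
        w = mha.attention_weights(x, x)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_keys_share_weight(self):
        rng = np.random.default_rng(5)
        mha = MultiHeadAttention(rng, 4, 1)
        x = Tensor(np.tile(np.array([0.5, -0.3, 0.2, 0.9]), (1, 2, 1)))
        w = mha.attention_weights(x, x)
        np.testing.assert_allclose(w, 0.5, atol=1e-9)

    def test_width_must_divide_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(np.random.default_rng(0), 6, 4)

    def test_transformer_block_preserves_shape(self):
        rng = np.random.default_rng(6)
        block = TransformerBlock(rng, 8, 2, 16, dropout=0.0)
        x = Tensor(rng.normal(size=(3, 4, 8)))
        assert block(x).shape == (3, 4, 8)

    def test_layernorm_statistics(self):
        rng = np.random.default_rng(7)
        block = TransformerBlock(rng, 8, 2, 16, dropout=0.0)
        x = Tensor(rng.normal(size=(2, 3, 8)))
        out = block(x).data  # gamma=1, beta=0 at init -> raw normalized
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)

    def test_max_pool_halves_spatial_dims(self):
        x = Tensor(np.arange(32, dtype=float).reshape(1, 4, 4, 2))
        out = max_pool_2x2(x)
        assert out.shape == (1, 2, 2, 2)
        assert out.data[0, 0, 0, 0] == 10.0  # max of the top-left 2x2 block


class TestClassifier:
    def test_probabilities_sum_to_one_and_deterministic(self, trained_blob_model,
                                                        blob_data):
        X, _, _ = blob_data
        proba = trained_blob_model.predict_proba(X[:6])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((proba > 0) & (proba < 1))
        np.testing.assert_array_equal(proba,
                                      trained_blob_model.predict_proba(X[:6]))

    def test_training_reaches_separable_accuracy(self, trained_blob_model,
                                                 blob_data):
        X, y, _ = blob_data
        assert trained_blob_model.history_["accuracy"][-1] >= 0.9
        assert np.mean(trained_blob_model.predict(X) == y) >= 0.9

    def test_loss_history_finite(self, trained_blob_model):
        assert np.all(np.isfinite(trained_blob_model.history_["loss"]))
        assert (len(trained_blob_model.history_["loss"])
                == trained_blob_model.epochs)

    def test_same_seed_bit_identical_weights(self, blob_data):
        X, y, _ = blob_data
        kw = dict(DESK_HAETN, epochs=3, random_state=5)
        sub = np.r_[0:8, 20:28]  # both classes represented
        a = HAETNClassifier(**kw).fit(X[sub], y[sub])
        b = HAETNClassifier(**kw).fit(X[sub], y[sub])
        for p, q in zip(a._net.params(), b._net.params()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_checkpoint_roundtrip_identical_outputs(self, tmp_path,
                                                    trained_blob_model, blob_data):
        X, _, _ = blob_data
        path = tmp_path / "model.ckpt"
        trained_blob_model.save(path)
        back = HAETNClassifier.load(path)
        np.testing.assert_array_equal(
            trained_blob_model.predict_proba(X[:5]), back.predict_proba(X[:5])
        )

    def test_single_class_rejected(self, blob_data):
        X, _, _ = blob_data
        with pytest.raises(ValueError, match="two classes"):
            HAETNClassifier(**DESK_HAETN).fit(X[:8], np.zeros(8, dtype=int))

    def test_heads_must_divide_width(self, blob_data):
        X, y, _ = blob_data
        with pytest.raises(ValueError, match="divide"):
            HAETNClassifier(lstm_hidden=5, attn_heads=4, epochs=1).fit(X, y)


class TestGradCam:
    def test_heatmap_in_unit_range(self, trained_blob_model, blob_data):
        X, _, _ = blob_data
        heat = gradcam_map(trained_blob_model, X[25], 1)
        assert heat.shape == X[25].shape
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_unknown_class_rejected(self, trained_blob_model, blob_data):
        X, _, _ = blob_data
        with pytest.raises(ValueError, match="unknown target class"):
            gradcam_map(trained_blob_model, X[0], 7)

    def test_blob_quadrant_dominates(self, trained_blob_model, blob_data):
        from tests.conftest import quadrant_sums

        X, _, _ = blob_data
        hits = total = 0
        for i in range(20, 40):
            heat = gradcam_map(trained_blob_model, X[i], 1)
            for t in (2, 3):  # blob-bearing mid slices
                q = quadrant_sums(heat[t])
                total += 1
                hits += q[0] > max(q[1:])
        assert hits / total >= 0.8
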