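"""Transformer classifier: attention math, equivariance, channel-agnosticism,
gradients, and checkpointing."""

import math

import numpy as np
import pytest

from szdetect.model import (
    ChannelTransformer,
    ClassScore,
    ModelConfig,
    TrainedModel,
    scaled_dot_attention,
    tiny_config,
)
from szdetect.nn import (
    EncoderLayer,
    LayerNorm,
    MultiHeadAttention,
    softmax,
    softmax_cross_entropy,
)

TINY = tiny_config()


class TestScaledDotAttention:
    def test_single_token_returns_value_row(self):
        q = np.array([[1.0, 2.0]])
        out = scaled_dot_attention(q, q, np.array([[5.0, -3.0]]))
        np.testing.assert_allclose(out, [[5.0, -3.0]])

    def test_zero_query_uniform_weights(self, rng):
        V = rng.standard_normal((3, 4))
        out = scaled_dot_attention(np.zeros((2, 5)), rng.standard_normal((3, 5)), V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_two_token_integer_case_matches_hand_computation(self):
        """Elementwise evaluation with explicit exponentials, done inline."""
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = 1.0 / math.sqrt(2.0)
        # row 0 scores: (1*1+0*0)/sqrt2 = s, (1*0+0*1)/sqrt2 = 0
        w00 = math.exp(s) / (math.exp(s) + math.exp(0.0))
        w01 = 1.0 - w00
        expected = np.array(
            [
                [w00 * 1 + w01 * 3, w00 * 2 + w01 * 4],
                [w01 * 1 + w00 * 3, w01 * 2 + w00 * 4],  # symmetric scores
            ]
        )
        np.testing.assert_allclose(scaled_dot_attention(Q, K, V, d_k=2), expected, rtol=1e-12)

    def test_rows_are_probability_vectors(self, rng):
        Q, K = rng.standard_normal((4, 8)), rng.standard_normal((6, 8))
        w = softmax(Q @ K.T / np.sqrt(8))
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(rng.standard_normal((2, 3)), rng.standard_normal((2, 4)),
                                 rng.standard_normal((2, 4)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_attention(self, rng):
        d = 6
        mha = MultiHeadAttention(d, 1, rng)
        for lin in (mha.Wq, mha.Wk, mha.Wv, mha.Wo):
            lin.W.value = np.eye(d)
            lin.b.value = np.zeros(d)
        x = rng.standard_normal((1, 5, d))
        np.testing.assert_allclose(
            mha.forward(x)[0], scaled_dot_attention(x[0], x[0], x[0], d_k=d), rtol=1e-12
        )

    @pytest.mark.parametrize("tokens", [1, 2, 16, 20])
    def test_output_shape_preserved(self, rng, tokens):
        mha = MultiHeadAttention(16, 4, rng)
        x = rng.standard_normal((2, tokens, 16))
        assert mha.forward(x).shape == x.shape

    def test_token_permutation_equivariance(self, rng):
        mha = MultiHeadAttention(16, 4, rng)
        x = rng.standard_normal((1, 7, 16))
        perm = rng.permutation(7)
        np.testing.assert_allclose(mha.forward(x[:, perm]), mha.forward(x)[:, perm], atol=1e-10)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(10, 3, rng)


class TestEncoderLayer:
    def test_layernorm_rows_standardized_at_unit_affine(self, rng):
        ln = LayerNorm(32)
        y = ln.forward(rng.standard_normal((4, 5, 32)) * 3 + 1)
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-10)
        np.testing.assert_allclose(y.var(axis=-1), 1.0, atol=1e-4)

    def test_full_layer_permutation_equivariance(self, rng):
        layer = EncoderLayer(16, 4, 24, rng)
        x = rng.standard_normal((2, 9, 16))
        perm = rng.permutation(9)
        np.testing.assert_allclose(layer.forward(x[:, perm]), layer.forward(x)[:, perm],
                                   atol=1e-10)

    def test_default_config_has_eight_stacked_layers(self):
        net = ChannelTransformer(ModelConfig(), seed=0)
        assert len(net.layers) == 8


class TestForward:
    def test_default_head_sizes(self):
        cfg = ModelConfig()
        assert cfg.d_k == cfg.d_v == 128
        assert cfg.d_model == cfg.n_heads * cfg.d_k

    @pytest.mark.parametrize("channels", [1, 2, 4, 8, 16, 20])
    def test_probabilities_sum_to_one_any_channel_count(self, rng, channels):
        net = ChannelTransformer(TINY, seed=1)
        score = net.score_window(rng.standard_normal((channels, 100)))
        assert isinstance(score, ClassScore)
        assert abs(score.p_seizure + score.p_nonseizure - 1.0) < 1e-9

    def test_token0_readout_invariant_to_other_channel_order(self, rng):
        net = ChannelTransformer(TINY, seed=2)
        x = rng.standard_normal((8, 100))
        base = net.score_window(x)
        perm = np.concatenate([[0], 1 + rng.permutation(7)])
        permuted = net.score_window(x[perm])
        assert abs(base.p_seizure - permuted.p_seizure) < 1e-10

    def test_mean_pool_invariant_to_any_channel_order(self, rng):
        net = ChannelTransformer(tiny_config(readout="mean_pool"), seed=2)
        x = rng.standard_normal((8, 100))
        assert abs(net.score_window(x).p_seizure
                   - net.score_window(x[rng.permutation(8)]).p_seizure) < 1e-10

    def test_wrong_window_length_names_expected(self, rng):
        net = ChannelTransformer(TINY, seed=0)
        with pytest.raises(ValueError, match="L=100"):
            net.forward(rng.standard_normal((1, 4, 99)))


class TestGradients:
    def test_backprop_matches_numerical_gradients(self, rng):
        """Central-difference check through the full network."""
        cfg = ModelConfig(window_len=7, d_model=8, n_layers=2, n_heads=2, d_ff=10,
                          mlp2_hidden=5)
        net = ChannelTransformer(cfg, seed=3)
        x = rng.standard_normal((3, 4, 7))
        y = np.array([0, 1, 1])
        net.zero_grad()
        _, g = softmax_cross_entropy(net.forward(x), y)
        net.backward(g)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for p in net.parameters():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = softmax_cross_entropy(net.forward(x), y)[0]
                flat[i] = old - eps
                lm = softmax_cross_entropy(net.forward(x), y)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[i]) < 1e-6 + 1e-4 * (abs(num) + abs(gflat[i]))


class TestCheckpoint:
    def test_save_load_round_trip_predictions(self, rng, tmp_path):
        net = ChannelTransformer(TINY, seed=4)
        model = TrainedModel(config=TINY, network=net, record={"note": "untrained"})
        x = rng.standard_normal((5, 16, 100))
        path = model.save(tmp_path / "model.ckpt")
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(back.predict_proba(x), model.predict_proba(x))
        assert back.config == TINY
        assert back.record == {"note": "untrained"}


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(d_model=100, n_heads=3)
    with pytest.raises(ValueError):
        ModelConfig(readout="last_token")
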