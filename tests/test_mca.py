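"""Cross-attention fusion: initialization contract and formula oracles."""
import numpy as np
import pytest

from cgsnet.mca import (CrossAttentionWeights, MCABlock, MCAConfig, TokenTensor,
                        cross_attention, init_weights, map_from_tokens,
                        tokens_from_map, uniform_softmax_matrix)
from cgsnet.nn.tensor import Tensor


def brute_force_cross_attention(ctx, det, w):
    """Triple-loop evaluation of softmax(Q K^T / sqrt(d_k)) V W_P."""
    n, d = det.shape
    q = ctx @ w.W_Q
    k = det @ w.W_K
    v = det @ w.W_V
    out = np.zeros((n, d))
    for i in range(n):
        scores = np.array([q[i] @ k[j] / np.sqrt(w.d_k) for j in range(n)])
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        for j in range(n):
            out[i] += a[j] * v[j]
    return out @ w.W_P


class TestInitWeights:
    def test_zero_query_identity_keys_values_projection(self):
        w = init_weights(3)
        assert np.array_equal(w.W_Q, np.zeros((3, 3)))
        assert np.array_equal(w.W_K, np.eye(3))
        assert np.array_equal(w.W_V, np.eye(3))
        assert np.array_equal(w.W_P, np.eye(3))
        assert w.d_k == 3

    def test_entry_means(self):
        w = init_weights(5)
        assert w.W_Q.mean() == 0.0
        assert w.W_K.mean() == pytest.approx(1 / 5)

    def test_no_randomness(self):
        a, b = init_weights(4), init_weights(4)
        assert np.array_equal(a.W_Q, b.W_Q) and np.array_equal(a.W_P, b.W_P)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            init_weights(0)


class TestUniformSoftmax:
    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_entries_and_row_sums(self, n):
        m = uniform_softmax_matrix(n)
        assert np.allclose(m, 1.0 / n)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_equals_softmax_of_zero_matrix(self):
        z = np.zeros((6, 6))
        e = np.exp(z - z.max(axis=1, keepdims=True))
        soft = e / e.sum(axis=1, keepdims=True)
        assert np.abs(uniform_softmax_matrix(6) - soft).max() < 1e-15

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            uniform_softmax_matrix(0)


class TestCrossAttention:
    def test_closed_form_at_init_rows_equal_mean_detail_token(self):
        det = TokenTensor(np.array([[1.0, 2.0], [3.0, 4.0]]), (2, 1))
        ctx = TokenTensor(np.array([[9.0, -1.0], [0.5, 7.0]]), (2, 1))
        out = cross_attention(ctx, det, init_weights(2),
                              MCAConfig(residual=False))
        assert np.abs(out.tokens - np.array([[2.0, 3.0], [2.0, 3.0]])).max() < 1e-12

    @pytest.mark.parametrize("n,d", [(1, 1), (3, 2), (4, 8), (8, 5)])
    def test_init_output_rows_all_equal_column_means(self, n, d, rng):
        det = TokenTensor(rng.standard_normal((n, d)), (n, 1))
        ctx = TokenTensor(rng.standard_normal((n, d)), (n, 1))
        out = cross_attention(ctx, det, init_weights(d), MCAConfig(residual=False))
        want = np.tile(det.tokens.mean(axis=0), (n, 1))
        assert np.abs(out.tokens - want).max() < 1e-12

    def test_init_output_independent_of_context(self, rng):
        det = TokenTensor(rng.standard_normal((5, 3)), (5, 1))
        w = init_weights(3)
        outs = [cross_attention(TokenTensor(rng.standard_normal((5, 3)), (5, 1)),
                                det, w, MCAConfig(residual=False)).tokens
                for _ in range(3)]
        assert np.array_equal(outs[0], outs[1]) and np.array_equal(outs[1], outs[2])

    def test_matches_brute_force_on_random_weights(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 7))
            d = int(rng.integers(1, 5))
            det = TokenTensor(rng.standard_normal((n, d)), (n, 1))
            ctx = TokenTensor(rng.standard_normal((n, d)), (n, 1))
            w = CrossAttentionWeights(*(rng.standard_normal((d, d)) for _ in range(4)),
                                      d_k=d)
            fast = cross_attention(ctx, det, w, MCAConfig(residual=False)).tokens
            slow = brute_force_cross_attention(ctx.tokens, det.tokens, w)
            assert np.abs(fast - slow).max() < 1e-10

    def test_residual_adds_detail_tokens(self, rng):
        det = TokenTensor(rng.standard_normal((4, 3)), (4, 1))
        ctx = TokenTensor(rng.standard_normal((4, 3)), (4, 1))
        w = init_weights(3)
        plain = cross_attention(ctx, det, w, MCAConfig(residual=False)).tokens
        res = cross_attention(ctx, det, w, MCAConfig(residual=True)).tokens
        assert np.allclose(res, plain + det.tokens)

    def test_shape_mismatch_rejected(self, rng):
        det = TokenTensor(rng.standard_normal((4, 3)), (4, 1))
        ctx = TokenTensor(rng.standard_normal((5, 3)), (5, 1))
        with pytest.raises(ValueError):
            cross_attention(ctx, det, init_weights(3))


class TestTokenMapConversion:
    def test_row_major_convention(self):
        fm = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])
        tt = tokens_from_map(fm)
        assert np.array_equal(tt.tokens.ravel(), [1, 2, 3, 4])

    def test_round_trip_identity(self, rng):
        fm = rng.standard_normal((7, 5, 3))
        assert np.array_equal(map_from_tokens(tokens_from_map(fm)), fm)

    def test_mismatched_spatial_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            TokenTensor(rng.standard_normal((6, 2)), (2, 2))


class TestMCABlockGradients:
    def test_context_pathway_dormant_but_trainable(self, rng):
        """At init the output ignores the context numerically, yet the loss
        gradient w.r.t. the query weights is nonzero: the pathway can train."""
        blk = MCABlock(4, ffn_hidden=2, residual=True, rng=rng)
        det = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        ctx = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        ctx2 = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        out1 = blk(det, ctx)
        out2 = blk(det, ctx2)
        assert np.abs(out1.data - out2.data).max() <= 1e-8
        target = rng.standard_normal(out1.shape).astype(np.float32)
        loss = ((blk(det, ctx) - Tensor(target)) ** 2).mean()
        blk.zero_grad()
        loss.backward()
        assert blk.q.weight.grad is not None
        assert np.abs(blk.q.weight.grad).max() > 0

    def test_softmax_row_stochastic_for_arbitrary_weights(self, rng):
        tokens = rng.standard_normal((6, 6)) * 10
        shifted = tokens - tokens.max(axis=-1, keepdims=True)
        soft = np.exp(shifted) / np.exp(shifted).sum(axis=-1, keepdims=True)
        assert np.allclose(soft.sum(axis=-1), 1.0, atol=1e-12)
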