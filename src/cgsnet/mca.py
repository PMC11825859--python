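"""Multi-cross attention (MCA) fusion between detail and context features.

The fusion computes ``softmax(Q K^T / sqrt(d_k)) V W_P`` where the queries Q
come from the *context* branch and the keys/values K, V from the *detail*
branch.  Its defining property is the initialization: the query projection
starts at zero and the key/value/projection matrices start at identity, so
at initialization the attention output is independent of the context input
(softmax of an all-zero score matrix is the uniform row-stochastic matrix,
and each output row is then the mean detail token).  The context pathway is
nonetheless trainable, because the loss gradient with respect to the query
weights is generically nonzero.

Two surfaces are provided:

* a functional, numpy-level API (:func:`init_weights`, :func:`cross_attention`)
  used for closed-form and brute-force oracle checks in float64;
* :class:`MCABlock`, the autograd module embedded in the dual-encoder model,
  which adds input layer norms, a residual connection to the detail tokens
  and a zero-initialized bottleneck feed-forward refinement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor


# --------------------------------------------------------------------- types
@dataclass
class TokenTensor:
    """A flattened feature map: ``n`` spatial tokens of width ``d``."""

    tokens: np.ndarray           # (n, d)
    spatial_shape: tuple[int, int]

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens)
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 1:
            raise ValueError("tokens must be a (n >= 1, d) matrix")
        if not np.isfinite(self.tokens).all():
            raise ValueError("tokens must be finite")
        h, w = self.spatial_shape
        if h * w != self.tokens.shape[0]:
            raise ValueError(
                f"spatial_shape {self.spatial_shape} incompatible with "
                f"n={self.tokens.shape[0]} tokens")

    @property
    def n(self) -> int:
        return self.tokens.shape[0]

    @property
    def d(self) -> int:
        return self.tokens.shape[1]


@dataclass
class CrossAttentionWeights:
    """Square projection matrices for one cross-attention stage."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    W_P: np.ndarray
    d_k: int

    def __post_init__(self):
        d = self.W_Q.shape[0]
        for name in ("W_Q", "W_K", "W_V", "W_P"):
            m = getattr(self, name)
            if m.shape != (d, d):
                raise ValueError(f"{name} must be square {d}x{d}, got {m.shape}")
        if self.d_k != d:
            raise ValueError("d_k must equal the projection width d")


@dataclass
class MCAConfig:
    """Configuration of the four-stage MCA fusion."""

    residual: bool = True
    stage_dims: tuple[int, int, int, int] = (64, 128, 320, 512)
    # Bottleneck feed-forward width per stage; zero-initialized output layer.
    ffn_hidden: tuple[int, int, int, int] | None = None
    dropout: float = 0.0

    def __post_init__(self):
        if len(self.stage_dims) != 4:
            raise ValueError("MCA operates on exactly 4 encoder stages")
        if self.ffn_hidden is not None and len(self.ffn_hidden) != 4:
            raise ValueError("ffn_hidden must give 4 widths")


# ---------------------------------------------------------------- operations
def init_weights(d: int) -> CrossAttentionWeights:
    """Zero query / identity key, value and projection initialization."""
    if d < 1:
        raise ValueError("projection width d must be >= 1")
    return CrossAttentionWeights(
        W_Q=np.zeros((d, d)),
        W_K=np.eye(d),
        W_V=np.eye(d),
        W_P=np.eye(d),
        d_k=d,
    )


def uniform_softmax_matrix(n: int) -> np.ndarray:
    """softmax of an all-zero n x n score matrix: every entry 1/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.full((n, n), 1.0 / n)


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_attention(ctx: TokenTensor, det: TokenTensor,
                    w: CrossAttentionWeights, cfg: MCAConfig | None = None) -> TokenTensor:
    """Single-head cross attention of context queries over detail keys/values."""
    cfg = cfg or MCAConfig(residual=False)
    if ctx.d != det.d:
        raise ValueError(f"channel mismatch: ctx d={ctx.d}, det d={det.d}")
    if ctx.n != det.n:
        raise ValueError(f"token-count mismatch: ctx n={ctx.n}, det n={det.n}")
    q = ctx.tokens @ w.W_Q
    k = det.tokens @ w.W_K
    v = det.tokens @ w.W_V
    attn = _softmax_rows(q @ k.T / np.sqrt(w.d_k))
    out = attn @ v @ w.W_P
    if cfg.residual:
        out = out + det.tokens
    return TokenTensor(out, det.spatial_shape)


def tokens_from_map(feature_map: np.ndarray) -> TokenTensor:
    """Row-major flattening of an (H, W, d) feature map into tokens."""
    if feature_map.ndim != 3:
        raise ValueError("feature map must be (H, W, d)")
    h, w, d = feature_map.shape
    return TokenTensor(feature_map.reshape(h * w, d), (h, w))


def map_from_tokens(tt: TokenTensor) -> np.ndarray:
    h, w = tt.spatial_shape
    return tt.tokens.reshape(h, w, tt.d)


# ------------------------------------------------------------------- module
class MCABlock(nn.Module):
    """One fusion stage of the dual-encoder model.

    Input/output layout is NCHW.  The attention follows the functional
    definition above on layer-normalized tokens; the detail tokens are added
    back (residual, configurable) and a bottleneck feed-forward with a
    zero-initialized output layer refines the fused tokens.  All attention
    projections carry the zero/identity initialization, so the whole block
    is exactly context-independent at initialization.
    """

    def __init__(self, dim: int, ffn_hidden: int | None = None,
                 residual: bool = True, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.residual = residual
        self.norm_ctx = nn.LayerNorm(dim)
        self.norm_det = nn.LayerNorm(dim)
        self.q = nn.Linear(dim, dim, rng=rng)
        self.k = nn.Linear(dim, dim, rng=rng)
        self.v = nn.Linear(dim, dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        # zero query / identity keys, values, projection; zero biases
        self.q.weight.data = np.zeros((dim, dim), dtype=np.float32)
        self.k.weight.data = np.eye(dim, dtype=np.float32)
        self.v.weight.data = np.eye(dim, dtype=np.float32)
        self.proj.weight.data = np.eye(dim, dtype=np.float32)
        self.drop = nn.Dropout2d(dropout)
        if ffn_hidden:
            self.ffn1 = nn.Linear(dim, ffn_hidden, rng=rng)
            self.ffn2 = nn.Linear(ffn_hidden, dim, rng=rng)
            self.ffn2.weight.data = np.zeros((dim, ffn_hidden), dtype=np.float32)
        else:
            self.ffn1 = None
            self.ffn2 = None

    def forward(self, det_map: Tensor, ctx_map: Tensor) -> Tensor:
        n, c, h, w = det_map.shape
        if ctx_map.shape != det_map.shape:
            raise ValueError("detail/context feature shapes must match")
        det = det_map.reshape(n, c, h * w).transpose(0, 2, 1)   # N, n_tok, d
        ctx = ctx_map.reshape(n, c, h * w).transpose(0, 2, 1)
        q = self.q(self.norm_ctx(ctx))
        k = self.k(self.norm_det(det))
        v = self.v(self.norm_det(det))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.dim))
        out = self.proj(scores.softmax(-1) @ v)
        fused = det + out if self.residual else out
        if self.ffn1 is not None:
            fused = fused + self.ffn2(self.ffn1(fused).gelu())
        fused = fused.transpose(0, 2, 1).reshape(n, c, h, w)
        return self.drop(fused)
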