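"""Hierarchical mix-transformer (MiT) encoder.

Four stages with overlapped patch merging (stride-4 stem, then stride-2
merges), efficient self-attention with per-stage sequence-reduction ratios,
and a mix feed-forward containing a 3x3 depthwise convolution.  Stage
recipes follow the published B1/B2 configurations; a ``test_tiny`` recipe
with depth 1 per stage keeps CPU tests fast.
"""
from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import functional as NF
from ..nn.tensor import Tensor


class OverlapPatchEmbed(nn.Module):
    def __init__(self, in_ch, dim, kernel, stride, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, dim, kernel, stride, padding=kernel // 2, rng=rng)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor):
        x = self.conv(x)                               # N, D, H, W
        n, d, h, w = x.shape
        t = x.reshape(n, d, h * w).transpose(0, 2, 1)  # tokens
        return self.norm(t), (h, w)


class EfficientSelfAttention(nn.Module):
    """Self-attention with keys/values computed on a spatially reduced map."""

    def __init__(self, dim, heads, sr_ratio, rng):
        super().__init__()
        self.dim, self.heads, self.sr_ratio = dim, heads, sr_ratio
        self.head_dim = dim // heads
        self.q = nn.Linear(dim, dim, rng=rng)
        self.kv = nn.Linear(dim, 2 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, sr_ratio, rng=rng)
            self.sr_norm = nn.LayerNorm(dim)

    def _split(self, t: Tensor, n, length):
        return (t.reshape(n, length, self.heads, self.head_dim)
                 .transpose(0, 2, 1, 3))

    def forward(self, tokens: Tensor, hw):
        h, w = hw
        n, length, d = tokens.shape
        q = self._split(self.q(tokens), n, length)
        if self.sr_ratio > 1:
            m = tokens.transpose(0, 2, 1).reshape(n, d, h, w)
            m = self.sr(m)
            hr, wr = m.shape[2], m.shape[3]
            red = self.sr_norm(m.reshape(n, d, hr * wr).transpose(0, 2, 1))
        else:
            red = tokens
        lr = red.shape[1]
        kv = self.kv(red)
        k = self._split(kv[:, :, :d], n, lr)
        v = self._split(kv[:, :, d:], n, lr)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        out = scores.softmax(-1) @ v                  # N, heads, L, hd
        out = out.transpose(0, 2, 1, 3).reshape(n, length, d)
        return self.proj(out)


class MixFFN(nn.Module):
    def __init__(self, dim, hidden, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.dw = nn.DepthwiseConv2d(hidden, 3, 1, 1, rng=rng)
        self.fc2 = nn.Linear(hidden, dim, rng=rng)

    def forward(self, tokens: Tensor, hw):
        h, w = hw
        n, length, _ = tokens.shape
        x = self.fc1(tokens)
        hid = x.shape[2]
        m = x.transpose(0, 2, 1).reshape(n, hid, h, w)
        m = self.dw(m)
        x = m.reshape(n, hid, h * w).transpose(0, 2, 1)
        return self.fc2(x.gelu())


class MiTBlock(nn.Module):
    def __init__(self, dim, heads, sr_ratio, mlp_ratio, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, sr_ratio, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn = MixFFN(dim, dim * mlp_ratio, rng)

    def forward(self, tokens: Tensor, hw):
        tokens = tokens + self.attn(self.norm1(tokens), hw)
        tokens = tokens + self.ffn(self.norm2(tokens), hw)
        return tokens


MIT_RECIPES = {
    "b1": dict(dims=(64, 128, 320, 512), depths=(2, 2, 2, 2),
               heads=(1, 2, 5, 8), sr_ratios=(8, 4, 2, 1), mlp_ratio=4),
    "b2": dict(dims=(64, 128, 320, 512), depths=(3, 4, 6, 3),
               heads=(1, 2, 5, 8), sr_ratios=(8, 4, 2, 1), mlp_ratio=4),
    "test_tiny": dict(dims=(16, 32, 64, 96), depths=(1, 1, 1, 1),
                      heads=(1, 2, 4, 6), sr_ratios=(8, 4, 2, 1), mlp_ratio=2),
}


class MiTEncoder(nn.Module):
    """Returns the four stage feature maps (NCHW) at strides 4/8/16/32."""

    family = "mit"

    def __init__(self, variant: str = "b1", in_ch: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        r = MIT_RECIPES[variant]
        self.variant = variant
        self.stage_dims = r["dims"]
        dims = r["dims"]
        embed_specs = [(in_ch, dims[0], 7, 4)] + [
            (dims[i], dims[i + 1], 3, 2) for i in range(3)]
        for i, (ci, co, k, s) in enumerate(embed_specs):
            setattr(self, f"embed{i}", OverlapPatchEmbed(ci, co, k, s, rng))
            blocks = [MiTBlock(dims[i], r["heads"][i], r["sr_ratios"][i],
                               r["mlp_ratio"], rng) for _ in range(r["depths"][i])]
            for j, b in enumerate(blocks):
                setattr(self, f"stage{i}_block{j}", b)
            setattr(self, f"norm{i}", nn.LayerNorm(dims[i]))
        self.depths = r["depths"]

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for i in range(4):
            tokens, (h, w) = getattr(self, f"embed{i}")(x)
            for j in range(self.depths[i]):
                tokens = getattr(self, f"stage{i}_block{j}")(tokens, (h, w))
            tokens = getattr(self, f"norm{i}")(tokens)
            x = tokens.transpose(0, 2, 1).reshape(
                tokens.shape[0], tokens.shape[2], h, w)
            feats.append(x)
        return feats
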