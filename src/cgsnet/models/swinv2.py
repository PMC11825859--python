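"""SwinV2 hierarchical encoder.

Windowed attention with scaled cosine similarity, a continuous relative
position bias produced by a small MLP on log-spaced coordinates, residual
post-normalization, and patch-merging downsampling — the published Tiny and
Small stage recipes plus a depth-1 ``test_tiny`` recipe for CPU tests.
"""
from __future__ import annotations

import numpy as np

from .. import nn
from ..nn.tensor import Tensor, concat, pad2d, roll2d


def _relative_coords_table(window: int) -> np.ndarray:
    """(2w-1)^2 x 2 table of log-spaced normalized relative coordinates."""
    r = np.arange(-(window - 1), window, dtype=np.float64)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    table = np.stack([yy, xx], axis=-1)
    if window > 1:
        table = table / (window - 1)
    table = table * 8
    table = np.sign(table) * np.log2(np.abs(table) + 1.0) / np.log2(8)
    return table.reshape(-1, 2).astype(np.float32)


def _relative_position_index(window: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij"))                # 2, w, w
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]                    # 2, ww, ww
    rel = rel.transpose(1, 2, 0) + (window - 1)
    return (rel[:, :, 0] * (2 * window - 1) + rel[:, :, 1]).astype(np.int64)


class WindowAttention(nn.Module):
    def __init__(self, dim, heads, window, rng):
        super().__init__()
        self.dim, self.heads, self.window = dim, heads, window
        self.head_dim = dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, bias=False, rng=rng)
        self.q_bias = nn.Parameter(np.zeros(dim))
        self.v_bias = nn.Parameter(np.zeros(dim))
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.logit_scale = nn.Parameter(np.full(heads, np.log(10.0)))
        self.cpb_fc1 = nn.Linear(2, 512, rng=rng)
        self.cpb_fc2 = nn.Linear(512, heads, bias=False, rng=rng)
        self.register_buffer("coords_table", _relative_coords_table(window))
        self.register_buffer("rel_index", _relative_position_index(window))

    def _cpb(self, window: int):
        """Relative-position bias lookup tables for a given window size."""
        if window == self.window:
            return self.coords_table, self.rel_index
        cache = getattr(self, "_cpb_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_cpb_cache", cache)
        if window not in cache:
            cache[window] = (_relative_coords_table(window),
                             _relative_position_index(window))
        return cache[window]

    def forward(self, x: Tensor, mask: np.ndarray | None = None,
                window: int | None = None) -> Tensor:
        nw, ww, d = x.shape
        window = window or self.window
        zeros = Tensor(np.zeros(d, dtype=np.float32))
        qkv = self.qkv(x) + concat([self.q_bias, zeros, self.v_bias], 0)
        qkv = (qkv.reshape(nw, ww, 3, self.heads, self.head_dim)
                  .transpose(2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]                    # nw, h, ww, hd
        qn = q * ((q * q).sum(-1, keepdims=True) + 1e-12) ** -0.5
        kn = k * ((k * k).sum(-1, keepdims=True) + 1e-12) ** -0.5
        scale = self.logit_scale.clip(hi=float(np.log(100.0))).exp()
        attn = (qn @ kn.transpose(0, 1, 3, 2)) * scale.reshape(1, -1, 1, 1)
        table, index = self._cpb(window)
        bias = 16.0 * self.cpb_fc2(self.cpb_fc1(Tensor(table)).relu()).sigmoid()
        bias = bias[index.reshape(-1)].reshape(ww, ww, self.heads)
        attn = attn + bias.transpose(2, 0, 1).reshape(1, self.heads, ww, ww)
        if mask is not None:
            nmask = mask.shape[0]
            attn = (attn.reshape(nw // nmask, nmask, self.heads, ww, ww)
                    + Tensor(mask[:, None, :, :].astype(np.float32)))
            attn = attn.reshape(nw, self.heads, ww, ww)
        out = attn.softmax(-1) @ v
        out = out.transpose(0, 2, 1, 3).reshape(nw, ww, d)
        return self.proj(out)


class SwinBlock(nn.Module):
    def __init__(self, dim, heads, window, shift, mlp_ratio, rng):
        super().__init__()
        self.dim, self.window, self.shift = dim, window, shift
        self.attn = WindowAttention(dim, heads, window, rng)
        self.norm1 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, dim * mlp_ratio, rng=rng)
        self.fc2 = nn.Linear(dim * mlp_ratio, dim, rng=rng)
        self.norm2 = nn.LayerNorm(dim)
        self._mask_cache: dict[tuple[int, int], np.ndarray | None] = {}

    def _mask(self, h, w, ws):
        key = (h, w, ws)
        if key in self._mask_cache:
            return self._mask_cache[key]
        sh = self.shift
        img = np.zeros((h, w))
        cnt = 0
        for hs in (slice(0, -ws), slice(-ws, -sh), slice(-sh, None)):
            for wsl in (slice(0, -ws), slice(-ws, -sh), slice(-sh, None)):
                img[hs, wsl] = cnt
                cnt += 1
        win = (img.reshape(h // ws, ws, w // ws, ws)
                  .transpose(0, 2, 1, 3).reshape(-1, ws * ws))
        mask = np.where(win[:, :, None] != win[:, None, :], -100.0, 0.0)
        self._mask_cache[key] = mask
        return mask

    def forward(self, x: Tensor, hw):
        h, w = hw
        n, length, d = x.shape
        ws = min(self.window, h, w)
        divisible = (h % ws == 0) and (w % ws == 0)
        shift = self.shift if (divisible and min(h, w) > ws) else 0
        shortcut = x
        m = x.transpose(0, 2, 1).reshape(n, d, h, w)
        ph = (-h) % ws
        pw = (-w) % ws
        if ph or pw:
            m = pad2d(m, (0, ph, 0, pw))
        hp, wp = h + ph, w + pw
        if shift:
            m = roll2d(m, (-shift, -shift))
        m = m.reshape(n, d, hp // ws, ws, wp // ws, ws)
        m = m.transpose(0, 2, 4, 3, 5, 1)                       # n, nh, nw, ws, ws, d
        windows = m.reshape(n * (hp // ws) * (wp // ws), ws * ws, d)
        mask = self._mask(hp, wp, ws) if shift else None
        out = self.attn(windows, mask, window=ws)
        out = out.reshape(n, hp // ws, wp // ws, ws, ws, d)
        out = out.transpose(0, 5, 1, 3, 2, 4).reshape(n, d, hp, wp)
        if shift:
            out = roll2d(out, (shift, shift))
        if ph or pw:
            out = out[:, :, :h, :w]
        out = out.reshape(n, d, length).transpose(0, 2, 1)
        x = shortcut + self.norm1(out)                          # post-norm
        x = x + self.norm2(self.fc2(self.fc1(x).gelu()))
        return x


class PatchMerging(nn.Module):
    def __init__(self, dim, rng):
        super().__init__()
        self.dim = dim
        self.reduction = nn.Linear(4 * dim, 2 * dim, bias=False, rng=rng)
        self.norm = nn.LayerNorm(2 * dim)

    def forward(self, x: Tensor, hw):
        h, w = hw
        n, length, d = x.shape
        m = x.reshape(n, h // 2, 2, w // 2, 2, d)
        m = m.transpose(0, 1, 3, 2, 4, 5).reshape(n, (h // 2) * (w // 2), 4 * d)
        return self.norm(self.reduction(m)), (h // 2, w // 2)


SWINV2_RECIPES = {
    "tiny": dict(embed_dim=96, depths=(2, 2, 6, 2), heads=(3, 6, 12, 24),
                 window=7, mlp_ratio=4),
    "small": dict(embed_dim=96, depths=(2, 2, 18, 2), heads=(3, 6, 12, 24),
                  window=7, mlp_ratio=4),
    "test_tiny": dict(embed_dim=16, depths=(1, 1, 1, 1), heads=(1, 2, 4, 8),
                      window=7, mlp_ratio=2),
}


class SwinV2Encoder(nn.Module):
    """Returns four stage feature maps (NCHW) at strides 4/8/16/32."""

    family = "swinv2"

    def __init__(self, variant: str = "tiny", in_ch: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        r = SWINV2_RECIPES[variant]
        self.variant = variant
        e = r["embed_dim"]
        self.stage_dims = (e, 2 * e, 4 * e, 8 * e)
        self.depths = r["depths"]
        self.patch_conv = nn.Conv2d(in_ch, e, 4, 4, rng=rng)
        self.patch_norm = nn.LayerNorm(e)
        for i in range(4):
            dim = self.stage_dims[i]
            for j in range(r["depths"][i]):
                shift = 0 if j % 2 == 0 else r["window"] // 2
                setattr(self, f"stage{i}_block{j}",
                        SwinBlock(dim, r["heads"][i], r["window"], shift,
                                  r["mlp_ratio"], rng))
            if i < 3:
                setattr(self, f"merge{i}", PatchMerging(dim, rng))
        self.norm = nn.LayerNorm(self.stage_dims[3])

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.patch_conv(x)
        n, d, h, w = x.shape
        tokens = self.patch_norm(x.reshape(n, d, h * w).transpose(0, 2, 1))
        hw = (h, w)
        feats = []
        for i in range(4):
            for j in range(self.depths[i]):
                tokens = getattr(self, f"stage{i}_block{j}")(tokens, hw)
            out = tokens if i < 3 else self.norm(tokens)
            dim = self.stage_dims[i]
            feats.append(out.transpose(0, 2, 1).reshape(n, dim, hw[0], hw[1]))
            if i < 3:
                tokens, hw = getattr(self, f"merge{i}")(tokens, hw)
        return feats
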