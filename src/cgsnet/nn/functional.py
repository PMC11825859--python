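"""Convolution and normalization primitives on the autograd tensor.

All spatial operators use NCHW layout.  Convolutions are im2col-based; the
transposed convolution is implemented as the adjoint scatter of the forward
convolution, which makes the two exactly consistent.
"""
from __future__ import annotations

import numpy as np

from .tensor import Tensor


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Sliding windows of a padded NCHW array -> (N, C, OH, OW, kh, kw) view."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def _col2im(cols: np.ndarray, hp: int, wp: int, kh: int, kw: int,
            sh: int, sw: int) -> np.ndarray:
    """Adjoint of :func:`_windows`: scatter-add (N, C, OH, OW, kh, kw) back."""
    n, c, oh, ow = cols.shape[:4]
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += cols[:, :, :, :, i, j]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int | tuple[int, int] = 1, padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D convolution (cross-correlation); weight shape (O, C, kh, kw)."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    o, c, kh, kw = weight.shape
    n, cin, h, w = x.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {c}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    win = _windows(xp, kh, kw, sh, sw)                       # N,C,OH,OW,kh,kw
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    wmat = weight.data.reshape(o, c * kh * kw)
    out = cols @ wmat.T                                      # N, OH*OW, O
    if bias is not None:
        out = out + bias.data
    out = out.transpose(0, 2, 1).reshape(n, o, oh, ow)
    rq = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def backward(g):
        gm = g.reshape(n, o, oh * ow).transpose(0, 2, 1)     # N, OH*OW, O
        if bias is not None and bias.requires_grad:
            bias._accum(gm.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.tensordot(gm, cols, axes=([0, 1], [0, 1]))  # O, C*kh*kw
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = gm @ wmat                                # N, OH*OW, C*kh*kw
            gcols = gcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = _col2im(gcols, h + 2 * ph, w + 2 * pw, kh, kw, sh, sw)
            x._accum(gxp[:, :, ph:ph + h, pw:pw + w])

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor._make(out, parents, backward, rq)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise convolution; weight shape (C, 1, kh, kw), groups == C."""
    c, _, kh, kw = weight.shape
    n, cin, h, w = x.shape
    if cin != c:
        raise ValueError("depthwise_conv2d channel mismatch")
    ph = pw = padding
    sh = sw = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if padding else x.data
    win = _windows(xp, kh, kw, sh, sw)                       # N,C,OH,OW,kh,kw
    oh, ow = win.shape[2], win.shape[3]
    wk = weight.data.reshape(c, kh, kw)
    out = np.einsum("nchwij,cij->nchw", win, wk, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]
    rq = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nchw,nchwij->cij", g, win, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = g[:, :, :, :, None, None] * wk[None, :, None, None, :, :]
            gxp = _col2im(np.ascontiguousarray(gcols), h + 2 * ph, w + 2 * pw,
                          kh, kw, sh, sw)
            x._accum(gxp[:, :, ph:ph + h, pw:pw + w])

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor._make(out, parents, backward, rq)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2, padding: int = 0) -> Tensor:
    """Transposed convolution; weight shape (Cin, Cout, kh, kw)."""
    cin, cout, kh, kw = weight.shape
    n, cx, h, w = x.shape
    if cx != cin:
        raise ValueError("conv_transpose2d channel mismatch")
    s, p = stride, padding
    hp = (h - 1) * s + kh
    wp = (w - 1) * s + kw
    wmat = weight.data.reshape(cin, cout * kh * kw)
    xm = x.data.reshape(n, cin, h * w).transpose(0, 2, 1)    # N, HW, Cin
    cols = (xm @ wmat).reshape(n, h, w, cout, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    full = _col2im(np.ascontiguousarray(cols), hp, wp, kh, kw, s, s)
    out = full[:, :, p:hp - p, p:wp - p]
    if bias is not None:
        out = out + bias.data[None, :, None, None]
    rq = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        gfull = np.zeros((n, cout, hp, wp), dtype=g.dtype)
        gfull[:, :, p:hp - p, p:wp - p] = g
        win = _windows(gfull, kh, kw, s, s)                  # N,Cout,H,W,kh,kw
        if weight.requires_grad:
            gw = np.einsum("nihw,nohwjk->iojk", x.data, win, optimize=True)
            weight._accum(gw)
        if x.requires_grad:
            gx = np.einsum("nohwjk,iojk->nihw", win, weight.data, optimize=True)
            x._accum(gx)

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor._make(out, parents, backward, rq)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return xc * inv * gamma + beta


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm
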