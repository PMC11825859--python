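"""Extended U-Net decoder.

A standard U-Net decoding path over the four encoder stage maps, extended by
two additional transposed-convolution stages so the output probability map
has the full input resolution (no downsampled ground truth is ever used).
Channel widths are configurable; the widths shipped in the model registry
are calibrated per encoder family (see the registry module).
"""
from __future__ import annotations

import numpy as np

from .. import nn
from ..nn.tensor import Tensor, concat


class DoubleConv(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, 1, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class UNetDecoder(nn.Module):
    """Consumes [s1, s2, s3, s4] (strides 4/8/16/32) and emits a full-res map."""

    def __init__(self, skip_channels, head_channels, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3, c4 = skip_channels
        u3, u2, u1, u0, uf = head_channels
        self.skip_channels = tuple(skip_channels)
        self.head_channels = tuple(head_channels)
        self.up3 = nn.ConvTranspose2d(c4, u3, 2, 2, rng=rng)
        self.dec3 = DoubleConv(u3 + c3, u3, rng)
        self.up2 = nn.ConvTranspose2d(u3, u2, 2, 2, rng=rng)
        self.dec2 = DoubleConv(u2 + c2, u2, rng)
        self.up1 = nn.ConvTranspose2d(u2, u1, 2, 2, rng=rng)
        self.dec1 = DoubleConv(u1 + c1, u1, rng)
        # two extra upsampling stages back to input resolution
        self.up0 = nn.ConvTranspose2d(u1, u0, 2, 2, rng=rng)
        self.dec0 = DoubleConv(u0, u0, rng)
        self.upf = nn.ConvTranspose2d(u0, uf, 2, 2, rng=rng)
        self.decf = DoubleConv(uf, uf, rng)
        self.head = nn.Conv2d(uf, 1, 1, rng=rng)
        self.drop = nn.Dropout2d(dropout)

    def forward(self, feats: list[Tensor]) -> Tensor:
        s1, s2, s3, s4 = feats
        x = self.dec3(concat([self.up3(s4), s3], axis=1))
        x = self.drop(x)
        x = self.dec2(concat([self.up2(x), s2], axis=1))
        x = self.drop(x)
        x = self.dec1(concat([self.up1(x), s1], axis=1))
        x = self.drop(x)
        x = self.dec0(self.up0(x))
        x = self.decf(self.upf(x))
        return self.head(x).sigmoid()
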