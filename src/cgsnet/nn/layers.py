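"""Neural-network modules over the autograd tensor."""
from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at +/- 2 std (resampling)."""
    out = rng.standard_normal(shape) * std
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.standard_normal(bad.sum()) * std
        bad = np.abs(out) > 2 * std
    return out.astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for mod_name, mod in self.named_modules(prefix):
            for p_name, p in mod._params.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name), p

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        return [m for _, m in self.named_modules()]

    # ----------------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for mod_name, mod in self.named_modules():
            for b_name, b in mod._buffers.items():
                out[(f"{mod_name}.{b_name}" if mod_name else b_name)] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = {}
        for mod_name, mod in self.named_modules():
            for b_name in mod._buffers:
                buffers[(f"{mod_name}.{b_name}" if mod_name else b_name)] = (mod, b_name)
        for name, value in state.items():
            if name in params:
                if params[name].shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for '{name}': "
                        f"{params[name].shape} vs {value.shape}")
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            elif name in buffers:
                mod, b_name = buffers[name]
                mod.register_buffer(b_name, np.asarray(value).copy())
            else:
                raise KeyError(f"unknown state entry '{name}'")

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def num_parameters(self, trainable_only: bool = True) -> int:
        return sum(p.size for p in self.parameters()
                   if p.requires_grad or not trainable_only)

    def checksum(self) -> float:
        """Order-stable fingerprint of all parameter values (for freeze tests)."""
        import hashlib
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return int.from_bytes(h.digest()[:8], "big") / 2**64

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._seq.append(m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * std))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        out = F.conv2d(x, self.weight, None, self.stride, self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = float(np.sqrt(2.0 / (kernel * kernel)))
        self.weight = Parameter(rng.standard_normal((channels, 1, kernel, kernel)) * std)
        self.bias = Parameter(np.zeros(channels))
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 2, stride: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.standard_normal((in_ch, out_ch, kernel, kernel)) * std)
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
            mu_t = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu_t
            var_t = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            xhat = xc * (var_t + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Dropout(Module):
    """Element dropout; shares a module-local generator, reseedable for tests."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * keep.astype(np.float32)


class Dropout2d(Dropout):
    """Channel dropout for NCHW maps."""

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        n, c = x.shape[:2]
        keep = (self.rng.random((n, c, 1, 1)) >= self.rate) / (1.0 - self.rate)
        return x * keep.astype(np.float32)


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


def seed_dropout(model: Module, seed: int):
    """Give every dropout module a deterministic, distinct stream."""
    for i, m in enumerate(model.modules()):
        if isinstance(m, Dropout):
            m.rng = np.random.default_rng((seed, i))
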