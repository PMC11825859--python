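"""Model configuration, construction, weight transfer and inference.

The registry pins, per encoder variant, the published encoder stage recipe
together with decoder head widths and MCA bottleneck widths calibrated so
that the trainable parameter counts of the single and dual models reproduce
the published parameter table at two-decimal (million) precision.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .. import nn
from ..mca import MCABlock, MCAConfig
from ..nn.tensor import Tensor
from .decoder import UNetDecoder
from .mit import MiTEncoder, MIT_RECIPES
from .swinv2 import SwinV2Encoder, SWINV2_RECIPES


# ------------------------------------------------------------------- configs
@dataclass
class EncoderConfig:
    family: str = "mit"                    # {mit, swinv2}
    variant: str = "b1"                    # {b1, b2, tiny, small, test_tiny}
    stage_dims: tuple[int, int, int, int] | None = None
    stage_strides: tuple[int, int, int, int] = (4, 8, 16, 32)
    pretrained_source: str | None = None

    def __post_init__(self):
        if self.family not in ("mit", "swinv2"):
            raise ValueError(f"unknown encoder family '{self.family}'")
        recipes = MIT_RECIPES if self.family == "mit" else SWINV2_RECIPES
        if self.variant not in recipes:
            raise ValueError(f"unknown {self.family} variant '{self.variant}'")
        if self.stage_dims is None:
            if self.family == "mit":
                self.stage_dims = tuple(recipes[self.variant]["dims"])
            else:
                e = recipes[self.variant]["embed_dim"]
                self.stage_dims = (e, 2 * e, 4 * e, 8 * e)


@dataclass
class DecoderConfig:
    skip_channels: tuple[int, int, int, int]
    head_channels: tuple[int, int, int, int, int]
    out_channels: int = 1
    dropout: float = 0.0


@dataclass
class ModelConfig:
    mode: str                              # {single_detail, single_context, dual}
    encoder: EncoderConfig
    decoder: DecoderConfig
    mca: MCAConfig | None = None
    input_size: int = 224

    def __post_init__(self):
        if self.mode not in ("single_detail", "single_context", "dual"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.mode == "dual" and self.mca is None:
            raise ValueError("dual mode requires an MCA configuration")


# Calibrated decoder head widths and MCA bottleneck widths per variant.
REGISTRY: dict[tuple[str, str], dict] = {
    ("mit", "b1"): dict(head=(192, 80, 48, 24, 16), ffn=(20, 40, 100, 160)),
    ("mit", "b2"): dict(head=(192, 80, 48, 24, 16), ffn=(20, 40, 100, 160)),
    ("swinv2", "tiny"): dict(head=(164, 88, 32, 24, 16), ffn=(32, 64, 128, 256)),
    ("swinv2", "small"): dict(head=(162, 80, 48, 24, 16), ffn=(32, 64, 128, 256)),
    ("mit", "test_tiny"): dict(head=(32, 24, 16, 12, 8), ffn=(4, 8, 16, 24)),
    ("swinv2", "test_tiny"): dict(head=(32, 24, 16, 12, 8), ffn=(4, 8, 16, 32)),
}


def default_config(family: str, variant: str, mode: str = "single_detail",
                   dropout: float = 0.0, residual: bool = True) -> ModelConfig:
    enc = EncoderConfig(family=family, variant=variant)
    entry = REGISTRY[(family, variant)]
    dec = DecoderConfig(skip_channels=enc.stage_dims,
                        head_channels=entry["head"], dropout=dropout)
    mca = None
    if mode == "dual":
        mca = MCAConfig(residual=residual, stage_dims=enc.stage_dims,
                        ffn_hidden=entry["ffn"], dropout=dropout)
    return ModelConfig(mode=mode, encoder=enc, decoder=dec, mca=mca)


# -------------------------------------------------------------------- models
def _make_encoder(cfg: EncoderConfig, rng) -> nn.Module:
    if cfg.family == "mit":
        enc = MiTEncoder(cfg.variant, rng=rng)
    else:
        enc = SwinV2Encoder(cfg.variant, rng=rng)
    if cfg.pretrained_source:
        state = dict(np.load(cfg.pretrained_source))
        enc.load_state_dict(state)
    return enc


class SingleSegModel(nn.Module):
    """One encoder + the extended U-Net decoder; sigmoid probability output."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.encoder = _make_encoder(config.encoder, rng)
        self.decoder = UNetDecoder(config.decoder.skip_channels,
                                   config.decoder.head_channels,
                                   config.decoder.dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        _check_size(x)
        prob = self.decoder(self.encoder(x))
        return prob.reshape(prob.shape[0], prob.shape[2], prob.shape[3])


class DualSegModel(nn.Module):
    """CGS-Net: detail + context encoders fused by per-stage MCA blocks."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.encoder_detail = _make_encoder(config.encoder, rng)
        self.encoder_context = _make_encoder(config.encoder, rng)
        mca_cfg = config.mca
        ffn = mca_cfg.ffn_hidden or (None,) * 4
        for i, d in enumerate(config.encoder.stage_dims):
            setattr(self, f"mca{i}", MCABlock(d, ffn[i], mca_cfg.residual,
                                              mca_cfg.dropout, rng))
        self.decoder = UNetDecoder(config.decoder.skip_channels,
                                   config.decoder.head_channels,
                                   config.decoder.dropout, rng)

    def mca_blocks(self) -> list[MCABlock]:
        return [getattr(self, f"mca{i}") for i in range(4)]

    def forward(self, detail: Tensor, context: Tensor) -> Tensor:
        detail, context = _as_tensor(detail), _as_tensor(context)
        _check_size(detail)
        if detail.shape != context.shape:
            raise ValueError("detail and context inputs must have equal shapes")
        det_feats = self.encoder_detail(detail)
        ctx_feats = self.encoder_context(context)
        fused = [getattr(self, f"mca{i}")(d, c)
                 for i, (d, c) in enumerate(zip(det_feats, ctx_feats))]
        prob = self.decoder(fused)
        return prob.reshape(prob.shape[0], prob.shape[2], prob.shape[3])


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    return Tensor(x)


def _check_size(x):
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError(f"expected NCHW RGB input, got shape {x.shape}")
    if x.shape[2] % 32 or x.shape[3] % 32:
        raise ValueError("input spatial dims must be divisible by 32")


# ---------------------------------------------------------------- operations
def build_single(config: ModelConfig, seed: int = 0) -> SingleSegModel:
    if config.mode not in ("single_detail", "single_context"):
        raise ValueError("build_single requires a single_* mode config")
    return SingleSegModel(config, np.random.default_rng(seed))


def build_cgsnet(config: ModelConfig, seed: int = 0) -> DualSegModel:
    if config.mode != "dual":
        raise ValueError("build_cgsnet requires a dual mode config")
    return DualSegModel(config, np.random.default_rng(seed))


def transfer_weights(single_detail: SingleSegModel, single_context: SingleSegModel,
                     dual: DualSegModel) -> DualSegModel:
    """Move pre-trained single-model weights into the dual model.

    Detail encoder <- level-2 single's encoder, context encoder <- level-3
    single's encoder, decoder <- level-2 single's decoder.  The MCA blocks
    keep their zero/identity initialization.
    """
    for src, dst, what in ((single_detail.encoder, dual.encoder_detail, "detail encoder"),
                           (single_context.encoder, dual.encoder_context, "context encoder"),
                           (single_detail.decoder, dual.decoder, "decoder")):
        src_state = src.state_dict()
        try:
            dst.load_state_dict(src_state)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"weight transfer failed for {what}: {exc}") from exc
    return dual


def count_parameters(model: nn.Module) -> float:
    """Trainable parameters in millions, rounded to 2 decimals."""
    return round(model.num_parameters(trainable_only=True) / 1e6, 2)


def predict_patch(model: nn.Module, pair) -> np.ndarray:
    """Probability map for one patch pair (dual) or detail patch (single)."""
    model.eval()
    det = _image_to_input(pair.detail_image)
    if isinstance(model, DualSegModel):
        ctx = _image_to_input(pair.context_image)
        out = model(det, ctx)
    else:
        out = model(det)
    model.train()
    return out.data[0]


def _image_to_input(img: np.ndarray) -> Tensor:
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim == 3 and arr.shape[2] == 3:
        arr = arr.transpose(2, 0, 1)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return Tensor(arr[None])


def wsi_inference(model: nn.Module, slide, stride: int = 224,
                  patch: int = 224) -> np.ndarray:
    """Sliding-window heatmap over a slide's detail level, averaging overlaps."""
    if stride > patch:
        raise ValueError("stride larger than the window leaves gaps")
    level2 = np.asarray(slide.level2_image, dtype=np.float32) / 255.0
    h, w = level2.shape[:2]
    heat = np.zeros((h, w), dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    ys = _tile_starts(h, patch, stride)
    xs = _tile_starts(w, patch, stride)
    model.eval()
    dual = isinstance(model, DualSegModel)
    level3 = np.asarray(slide.level3_image, dtype=np.float32) / 255.0 if dual else None
    for y in ys:
        for x in xs:
            det = level2[y:y + patch, x:x + patch]
            inp = Tensor(det.transpose(2, 0, 1)[None])
            if dual:
                cy, cx = (y + patch // 2) // 2, (x + patch // 2) // 2
                ctx = _crop_padded(level3, cy, cx, patch)
                out = model(inp, Tensor(ctx.transpose(2, 0, 1)[None]))
            else:
                out = model(inp)
            heat[y:y + patch, x:x + patch] += out.data[0]
            weight[y:y + patch, x:x + patch] += 1.0
    model.train()
    return (heat / np.maximum(weight, 1.0)).astype(np.float32)


def _tile_starts(extent: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - patch, 0) + 1, stride))
    if starts[-1] + patch < extent:
        starts.append(extent - patch)
    return starts


def _crop_padded(img: np.ndarray, cy: int, cx: int, size: int) -> np.ndarray:
    """Crop a size x size window centred at (cx, cy), edge-padding at borders."""
    half = size // 2
    h, w = img.shape[:2]
    y0, x0 = cy - half, cx - half
    ys = np.clip(np.arange(y0, y0 + size), 0, h - 1)
    xs = np.clip(np.arange(x0, x0 + size), 0, w - 1)
    return img[np.ix_(ys, xs)]


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: nn.Module, path: str | Path):
    """Weight archive (.npz) plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    cfg = model.config
    side = {
        "mode": cfg.mode,
        "encoder": asdict(cfg.encoder),
        "decoder": asdict(cfg.decoder),
        "mca": asdict(cfg.mca) if cfg.mca else None,
        "input_size": cfg.input_size,
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_checkpoint(path: str | Path):
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    enc = EncoderConfig(**{**side["encoder"],
                           "stage_dims": tuple(side["encoder"]["stage_dims"]),
                           "stage_strides": tuple(side["encoder"]["stage_strides"])})
    dec = DecoderConfig(skip_channels=tuple(side["decoder"]["skip_channels"]),
                        head_channels=tuple(side["decoder"]["head_channels"]),
                        out_channels=side["decoder"]["out_channels"],
                        dropout=side["decoder"]["dropout"])
    mca = None
    if side["mca"]:
        mca = MCAConfig(residual=side["mca"]["residual"],
                        stage_dims=tuple(side["mca"]["stage_dims"]),
                        ffn_hidden=tuple(side["mca"]["ffn_hidden"]),
                        dropout=side["mca"]["dropout"])
    cfg = ModelConfig(mode=side["mode"], encoder=enc, decoder=dec, mca=mca,
                      input_size=side["input_size"])
    model = build_cgsnet(cfg) if cfg.mode == "dual" else build_single(cfg)
    state = dict(np.load(path.with_suffix(".npz")))
    model.load_state_dict(state)
    return model
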