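"""Multi-modal residual encoder-decoder backbone.

One residual encoder per MRI modality feeds a per-modality atrous spatial
pyramid (ASPP) bottleneck; the per-modality bottleneck maps are merged by a
residual convolution and a transposed-convolution decoder restores full
resolution, concatenating a skip bundle from the encoders at every level.
With the hybrid attentional fusion block (HAFB) enabled the skip bundle is
the fused 3C-channel map, so decoder width does not grow with the number
of modalities; without it the bundle is the plain channel concatenation of
the per-modality skips and the decoder widens proportionally. A
single-modal baseline mode runs one encoder over channel-stacked
modalities.

Channel plan
------------
Encoder layer ``l`` (0-based) outputs ``base_filters * 2**l`` channels; the
ASPP keeps its input width. The merged bottleneck has ``2 * C_last``
channels with HAFB and ``n * C_last`` without (n = number of encoders), and
decoder level ``l`` mirrors the encoder width times the same factor. This
makes the total parameter count exactly affine in the modality count with
HAFB and exactly quadratic without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .nn import Tensor
from .fusion import HAFB

__all__ = [
    "NetworkConfig",
    "LayerChannelPlan",
    "FeaturePyramid",
    "ConvBlock",
    "ResConv",
    "Encoder",
    "ASPP",
    "HybridFusionNet",
    "build_network",
    "count_parameters",
    "layer_plan",
]


@dataclass
class NetworkConfig:
    """Architectural hyperparameters of the segmentation network."""

    n_modalities: int = 4
    n_layers: int = 4
    base_filters: int = 32
    n_classes: int = 4
    aspp_dilations: tuple[int, ...] = (1, 6, 12, 18)
    dropout_rate: float = 0.2
    use_hafb: bool = True
    multi_modal: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.n_modalities < 1:
            raise ValueError("n_modalities must be >= 1")
        dil = tuple(int(d) for d in self.aspp_dilations)
        if any(d < 1 for d in dil) or len(set(dil)) != len(dil):
            raise ValueError("aspp_dilations must be positive and distinct")
        self.aspp_dilations = dil

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class LayerChannelPlan:
    encoder_out: list[int]
    bottleneck: int
    decoder_out: list[int]
    skip_bundle: list[int]


@dataclass
class FeaturePyramid:
    """Per-modality skip maps and post-ASPP bottleneck maps."""

    skips: list[list[Tensor]] = field(default_factory=list)  # [modality][layer]
    bottleneck: list[Tensor] = field(default_factory=list)  # [modality]


def layer_plan(cfg: NetworkConfig) -> LayerChannelPlan:
    enc = [cfg.base_filters * 2**l for l in range(cfg.n_layers)]
    n_eff = cfg.n_modalities if cfg.multi_modal else 1
    c_last = enc[-1]
    if cfg.use_hafb:
        bottleneck = 2 * c_last
        decoder = list(enc)
        skip = [3 * c for c in enc]
    else:
        bottleneck = n_eff * c_last
        decoder = [n_eff * c for c in enc]
        skip = [n_eff * c for c in enc]
    return LayerChannelPlan(enc, bottleneck, decoder, skip)


class ConvBlock(nn.Module):
    """3x3 convolution (size-preserving, no bias) -> batch norm -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class ResConv(nn.Module):
    """Residual double convolution: 1x1 projection + Conv(DP(Conv(x)))."""

    def __init__(self, in_ch: int, out_ch: int, dropout_rate: float, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, padding=0, bias=True)
        self.conv1 = ConvBlock(in_ch, out_ch, rng)
        self.dp = nn.Dropout(dropout_rate, rng)
        self.conv2 = ConvBlock(out_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(x) + self.conv2(self.dp(self.conv1(x)))


class Encoder(nn.Module):
    """Stack of ResConv + 2x2 max-pool layers for one modality."""

    def __init__(self, in_ch: int, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        plan = layer_plan(cfg)
        layers = []
        prev = in_ch
        for out in plan.encoder_out:
            layers.append(ResConv(prev, out, cfg.dropout_rate, rng))
            prev = out
        self.layers = nn.ModuleList(layers)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Return (final pooled map, pre-pool skip maps, shallowest first)."""
        h, w = x.shape[2:]
        if h % 2 ** len(self.layers) or w % 2 ** len(self.layers):
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^{len(self.layers)}"
            )
        skips = []
        for layer in self.layers:
            x = layer(x)
            skips.append(x)
            x = nn.max_pool2x2(x)
        return x, skips


class ASPP(nn.Module):
    """Atrous spatial pyramid: parallel dilated 3x3 branches + a pooled branch.

    Each dilation branch keeps the input width; a global-average-pooling
    branch (1x1 conv, broadcast back) adds image-level context. Branch
    outputs are concatenated and projected back to the input width.
    """

    def __init__(self, channels: int, dilations: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        self.branches = nn.ModuleList(
            [DilatedBlock(channels, channels, d, rng) for d in dilations]
        )
        self.pool_conv = nn.Conv2d(channels, channels, 1, rng, padding=0, bias=True)
        self.project = ConvBlock_1x1(channels * (len(dilations) + 1), channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2:]
        outs = [b(x) for b in self.branches]
        pooled = self.pool_conv(x.mean(axis=(2, 3), keepdims=True)).relu()
        outs.append(pooled.broadcast_spatial(h, w))
        return self.project(nn.concat(outs, axis=1))


class DilatedBlock(nn.Module):
    """Dilated 3x3 convolution -> BN -> ReLU (padding preserves size)."""

    def __init__(self, in_ch: int, out_ch: int, dilation: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng, dilation=dilation, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class ConvBlock_1x1(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, rng, padding=0, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class HybridFusionNet(nn.Module):
    """The full encoder/ASPP/fusion/decoder segmentation network."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        plan = layer_plan(cfg)
        self.plan = plan
        n_enc = cfg.n_modalities if cfg.multi_modal else 1
        in_ch = 1 if cfg.multi_modal else cfg.n_modalities
        self.encoders = nn.ModuleList([Encoder(in_ch, cfg, rng) for _ in range(n_enc)])
        c_last = plan.encoder_out[-1]
        self.aspps = nn.ModuleList(
            [ASPP(c_last, cfg.aspp_dilations, rng) for _ in range(n_enc)]
        )
        self.merge = ResConv(n_enc * c_last, plan.bottleneck, cfg.dropout_rate, rng)
        if cfg.use_hafb:
            self.hafbs = nn.ModuleList([HAFB(c, rng) for c in plan.encoder_out])
        # decoder, deepest level first
        ups, resconvds = [], []
        prev = plan.bottleneck
        for l in range(cfg.n_layers - 1, -1, -1):
            ups.append(nn.ConvTranspose2d(prev, plan.decoder_out[l], rng))
            resconvds.append(
                ResConv(
                    plan.decoder_out[l] + plan.skip_bundle[l],
                    plan.decoder_out[l],
                    cfg.dropout_rate,
                    rng,
                )
            )
            prev = plan.decoder_out[l]
        self.ups = nn.ModuleList(ups)
        self.resconvds = nn.ModuleList(resconvds)
        self.end_conv = nn.Conv2d(plan.decoder_out[0], cfg.n_classes, 3, rng, bias=True)

    # -- pieces ----------------------------------------------------------

    def encode(self, x: Tensor) -> FeaturePyramid:
        """Run every encoder + its ASPP; returns skips and bottleneck maps."""
        if x.shape[1] != self.cfg.n_modalities:
            raise ValueError(
                f"expected {self.cfg.n_modalities} modalities, got {x.shape[1]}"
            )
        pyramid = FeaturePyramid()
        for i, (enc, aspp) in enumerate(zip(self.encoders, self.aspps)):
            xi = self._modality_input(x, i)
            pooled, skips = enc(xi)
            pyramid.skips.append(skips)
            pyramid.bottleneck.append(aspp(pooled))
        return pyramid

    def _modality_input(self, x: Tensor, i: int) -> Tensor:
        if not self.cfg.multi_modal:
            return x
        n, m, h, w = x.shape
        # slice one modality as a single-channel image
        xi = Tensor(x.data[:, i : i + 1])
        if x.requires_grad or x._parents:
            # inputs never need gradients in this package; keep it simple
            raise NotImplementedError("gradients w.r.t. network inputs are unsupported")
        return xi

    def skip_bundle(self, pyramid: FeaturePyramid, layer: int) -> Tensor:
        maps = [skips[layer] for skips in pyramid.skips]
        if self.cfg.use_hafb:
            return self.hafbs[layer](maps)
        return maps[0] if len(maps) == 1 else nn.concat(maps, axis=1)

    def decode(self, pyramid: FeaturePyramid) -> Tensor:
        y = self.merge(
            pyramid.bottleneck[0]
            if len(pyramid.bottleneck) == 1
            else nn.concat(pyramid.bottleneck, axis=1)
        )
        for step, l in enumerate(range(self.cfg.n_layers - 1, -1, -1)):
            y = self.ups[step](y)
            y = nn.concat([y, self.skip_bundle(pyramid, l)], axis=1)
            y = self.resconvds[step](y)
        return self.end_conv(y)

    def forward(self, x: Tensor) -> Tensor:
        """(N, n_modalities, H, W) -> class logits (N, n_classes, H, W)."""
        return self.decode(self.encode(x))


def build_network(cfg: NetworkConfig) -> HybridFusionNet:
    return HybridFusionNet(cfg)


# -- parameter accounting -------------------------------------------------


def _conv_params(in_ch: int, out_ch: int, k: int, bias: bool) -> int:
    return k * k * in_ch * out_ch + (out_ch if bias else 0)


def _conv_block_params(in_ch: int, out_ch: int, k: int = 3) -> int:
    # conv without bias + batch-norm scale and shift
    return _conv_params(in_ch, out_ch, k, bias=False) + 2 * out_ch


def _res_conv_params(in_ch: int, out_ch: int) -> int:
    return (
        _conv_params(in_ch, out_ch, 1, bias=True)
        + _conv_block_params(in_ch, out_ch)
        + _conv_block_params(out_ch, out_ch)
    )


def _aspp_params(channels: int, n_dilations: int) -> int:
    branches = n_dilations * _conv_block_params(channels, channels)
    pool = _conv_params(channels, channels, 1, bias=True)
    project = _conv_block_params(channels * (n_dilations + 1), channels, k=1)
    return branches + pool + project


def _attention_params(c: int) -> int:
    # phi1: 3C->C, phi2: C->3C, phi3: 3C->3C, all 3x3 with bias
    return (
        _conv_params(3 * c, c, 3, bias=True)
        + _conv_params(c, 3 * c, 3, bias=True)
        + _conv_params(3 * c, 3 * c, 3, bias=True)
    )


def count_parameters(cfg: NetworkConfig) -> int:
    """Exact learnable-value count of the assembled network, by shape algebra.

    Matches ``HybridFusionNet(cfg).num_parameters()`` without allocating
    any weights, so it is cheap even for wide configurations.
    """
    plan = layer_plan(cfg)
    n_enc = cfg.n_modalities if cfg.multi_modal else 1
    in_ch = 1 if cfg.multi_modal else cfg.n_modalities
    total = 0
    # encoders
    prev = in_ch
    enc_one = 0
    for out in plan.encoder_out:
        enc_one += _res_conv_params(prev, out)
        prev = out
    total += n_enc * enc_one
    # per-modality ASPP
    total += n_enc * _aspp_params(plan.encoder_out[-1], len(cfg.aspp_dilations))
    # bottleneck merge
    total += _res_conv_params(n_enc * plan.encoder_out[-1], plan.bottleneck)
    # fusion blocks
    if cfg.use_hafb:
        total += sum(_attention_params(c) for c in plan.encoder_out)
    # decoder
    prev = plan.bottleneck
    for l in range(cfg.n_layers - 1, -1, -1):
        total += prev * plan.decoder_out[l] * 4  # 2x2 transposed conv
        total += _res_conv_params(plan.decoder_out[l] + plan.skip_bundle[l], plan.decoder_out[l])
        prev = plan.decoder_out[l]
    total += _conv_params(plan.decoder_out[0], cfg.n_classes, 3, bias=True)
    return total
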