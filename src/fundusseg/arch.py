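"""RSAP-Net: a U-shaped encoder-decoder for joint disc/cup segmentation.

The encoder is a residual CNN producing feature maps at five scales
(S/2 ... S/32 for an S x S input); the bottleneck holds a multi-branch
dilated-convolution block (MDC, cascaded dilation rates 1/2/5) and a global
information coding block (GIC, multi-size pooled one-channel summaries); the
decoder upsamples with transposed convolutions; and the three shallowest
encoder-decoder scale pairs are bridged by residual spatial-attention paths
(RSAP) instead of plain skip connections.  The output is a 3-channel logit
map (background / optic disc / optic cup) at the input resolution, trained
with the pixel-mean softmax cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "dilated_out_size",
    "mdc_receptive_field",
    "SpatialAttention",
    "ResidualBlock",
    "RSAPPath",
    "MDCBlock",
    "GICBlock",
    "RSAPNet",
    "cross_entropy_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_stage_channels`` are the widths of the five encoder scale maps
    (default: ``base_channels`` doubling per scale).  ``rsap_depths`` gives
    the residual-block count of the three bridge paths, shallowest first;
    depth 0 removes a bridge (the plain encoder-decoder ablation baseline).
    """

    input_size: int = 512
    base_channels: int = 32
    encoder_stage_channels: tuple | None = None
    mdc_dilations: tuple = (1, 2, 5)
    gic_pool_sizes: tuple = (5, 6)
    gic_conv_specs: tuple = ((2, 2), (3, 3))
    rsap_depths: tuple = (3, 2, 1)
    n_classes: int = 3
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.n_classes != 3:
            raise ValueError("the segmentation task has exactly 3 classes")
        if len(self.rsap_depths) != 3:
            raise ValueError("rsap_depths needs exactly 3 entries")
        if any(d < 0 for d in self.rsap_depths):
            raise ValueError("rsap_depths must be nonnegative")
        if self.encoder_stage_channels is None:
            self.encoder_stage_channels = tuple(
                self.base_channels * 2 ** i for i in range(5))
        self.encoder_stage_channels = tuple(self.encoder_stage_channels)
        if len(self.encoder_stage_channels) != 5:
            raise ValueError("need one channel width per encoder scale (5)")


def dilated_out_size(w_in: int, p: int, d: int, k: int, s: int) -> int:
    """Output width of a dilated convolution:
    floor((w_in + 2p - d(k-1) - 1) / s) + 1."""
    for name, v in (("w_in", w_in), ("d", d), ("k", k), ("s", s)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer")
    if int(p) != p or p < 0:
        raise ValueError("p must be a nonnegative integer")
    return nn.conv_out_size(int(w_in), int(p), int(d), int(k), int(s))


def mdc_receptive_field(dilations=(1, 2, 5), k: int = 3) -> int:
    """Effective receptive field of the deepest MDC cascade branch:
    1 + (k-1) * sum(dilations)."""
    return 1 + (k - 1) * int(sum(dilations))


class ConvBNAct(nn.Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=0, dil=1, slope=0.01):
        self.conv = nn.Conv2d(cin, cout, k, rng, stride=stride, pad=pad,
                              dil=dil, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions (BN + LeakyReLU) with an additive identity
    shortcut; a 1x1 projection aligns channels when they change."""

    def __init__(self, cin, cout, rng, slope=0.01):
        self.conv1 = ConvBNAct(cin, cout, 3, rng, pad=1, slope=slope)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, pad=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        self.proj = (nn.Conv2d(cin, cout, 1, rng, bias=False)
                     if cin != cout else None)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        y = self.bn2(self.conv2(self.conv1(x)))
        shortcut = self.proj(x) if self.proj is not None else x
        return self.act(y + shortcut)


class SpatialAttention(nn.Module):
    """Channel-wise max and average pooling, concatenated to 2 planes,
    convolved 3x3 to one plane and passed through LeakyReLU; yields a
    1 x H x W attention map at the input's spatial size."""

    def __init__(self, rng, slope=0.01):
        self.conv = nn.Conv2d(2, 1, 3, rng, pad=1, bias=True)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        pooled = nn.concat([nn.channel_max(x), nn.channel_mean(x)], axis=1)
        return self.act(self.conv(pooled))


class RSAPPath(nn.Module):
    """Residual spatial-attention bridge: ``depth`` residual blocks emulate
    the encoder's residual computation, then the block output G is modulated
    elementwise by its spatial-attention map; the result is added to the
    decoder feature map at the same scale."""

    def __init__(self, channels, depth, rng, slope=0.01):
        if depth < 1:
            raise ValueError("RSAP path depth must be >= 1")
        self.depth = depth
        self.blocks = [ResidualBlock(channels, channels, rng, slope)
                       for _ in range(depth)]
        self.attention = SpatialAttention(rng, slope)

    def forward(self, x):
        g = x
        for block in self.blocks:
            g = block(g)
        return g * self.attention(g)


class MDCBlock(nn.Module):
    """Multi-branch dilated convolution block (bottleneck context extractor).

    Four cascade branches over the input F: 3x3 d=d0; d0 -> d1; d0 -> d1 ->
    d2; and identity.  Each non-identity branch ends in a linear 1x1
    convolution; branch outputs are summed.  Padding p=d keeps the spatial
    size constant.
    """

    def __init__(self, channels, rng, dilations=(1, 2, 5), slope=0.01):
        if len(dilations) != 3:
            raise ValueError("MDC uses exactly three dilation rates")
        self.dilations = tuple(int(d) for d in dilations)
        d0, d1, d2 = self.dilations

        def dconv(d):
            return ConvBNAct(channels, channels, 3, rng, pad=d, dil=d,
                             slope=slope)

        self.branch_a = [dconv(d0)]
        self.branch_b = [dconv(d0), dconv(d1)]
        self.branch_c = [dconv(d0), dconv(d1), dconv(d2)]
        self.fuse_a = nn.Conv2d(channels, channels, 1, rng)
        self.fuse_b = nn.Conv2d(channels, channels, 1, rng)
        self.fuse_c = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x):
        outs = [x]
        for branch, fuse in ((self.branch_a, self.fuse_a),
                             (self.branch_b, self.fuse_b),
                             (self.branch_c, self.fuse_c)):
            y = x
            for layer in branch:
                y = layer(y)
            outs.append(fuse(y))
        total = outs[0]
        for y in outs[1:]:
            total = total + y
        return total


class GICBlock(nn.Module):
    """Global information coding block: two strided-convolution branches and
    two max-pooling branches, each reduced to a single channel by a 1x1
    convolution, bilinearly upsampled back and concatenated with the input
    (channel count grows by the number of branches, 4 by default)."""

    def __init__(self, channels, rng, pool_sizes=(5, 6),
                 conv_specs=((2, 2), (3, 3)), slope=0.01):
        self.pool_sizes = tuple(int(k) for k in pool_sizes)
        self.conv_specs = tuple((int(k), int(s)) for k, s in conv_specs)
        self.conv_branches = [ConvBNAct(channels, channels, k, rng, stride=s,
                                        slope=slope)
                              for k, s in self.conv_specs]
        n = len(self.conv_specs) + len(self.pool_sizes)
        self.squeeze = [nn.Conv2d(channels, 1, 1, rng) for _ in range(n)]
        self.n_branches = n

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        kernels = self.pool_sizes + tuple(k for k, _ in self.conv_specs)
        if min(h, w) < max(kernels):
            raise ValueError(
                f"GIC branch kernels {kernels} do not fit a {h}x{w} feature "
                "map; shrink gic_pool_sizes/gic_conv_specs for small inputs")
        maps = [x]
        idx = 0
        for branch in self.conv_branches:
            y = self.squeeze[idx](branch(x))
            maps.append(nn.bilinear_resize(y, (h, w)))
            idx += 1
        for k in self.pool_sizes:
            y = self.squeeze[idx](nn.max_pool2d(x, k))
            maps.append(nn.bilinear_resize(y, (h, w)))
            idx += 1
        return nn.concat(maps, axis=1)


class DecoderBlock(nn.Module):
    """Two 1x1 convolutions then a 3x3 stride-2 transposed convolution."""

    def __init__(self, cin, cout, rng, slope=0.01):
        self.conv1 = ConvBNAct(cin, cout, 1, rng, slope=slope)
        self.conv2 = ConvBNAct(cout, cout, 1, rng, slope=slope)
        self.up = nn.ConvTranspose2d(cout, cout, 3, rng, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        return self.act(self.bn(self.up(self.conv2(self.conv1(x)))))


class RSAPNet(nn.Module):
    """The full network; ``forward`` maps (N, 3, S, S) to (N, 3, S, S)
    logits and records the encoder scale-map shapes in
    ``encoder_scale_shapes_``."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0, c1, c2, c3, c4 = config.encoder_stage_channels
        slope = config.leaky_slope
        self.stem = ConvBNAct(3, c0, 3, rng, pad=1, slope=slope)
        self.stage1 = ResidualBlock(c0, c0, rng, slope)
        self.stage2 = ResidualBlock(c0, c1, rng, slope)
        self.stage3 = ResidualBlock(c1, c2, rng, slope)
        self.stage4 = ResidualBlock(c2, c3, rng, slope)
        self.pool = nn.MaxPool2d(2)
        self.bottleneck_in = ResidualBlock(c3, c4, rng, slope)
        self.mdc = MDCBlock(c4, rng, config.mdc_dilations, slope)
        self.gic = GICBlock(c4, rng, config.gic_pool_sizes,
                            config.gic_conv_specs, slope)
        extra = self.gic.n_branches
        self.dec1 = DecoderBlock(c4 + extra, c3, rng, slope)
        self.dec2 = DecoderBlock(c3, c2, rng, slope)
        self.dec3 = DecoderBlock(c2, c1, rng, slope)
        self.dec4 = DecoderBlock(c1, c0, rng, slope)
        depths = config.rsap_depths
        bridge_channels = (c0, c1, c2)  # shallowest first
        self.bridges = [RSAPPath(ch, d, rng, slope) if d > 0 else None
                        for ch, d in zip(bridge_channels, depths)]
        self.head_up = nn.ConvTranspose2d(c0, c0, 3, rng, bias=False)
        self.head_bn = nn.BatchNorm2d(c0)
        self.head_act = nn.LeakyReLU(slope)
        self.head = nn.Conv2d(c0, config.n_classes, 1, rng)

    @property
    def n_bridges(self) -> int:
        return sum(b is not None for b in self.bridges)

    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        s = x.shape[-1]
        if s != self.config.input_size or x.shape[-2] != s:
            raise ValueError(f"expected {self.config.input_size}-square "
                             f"input, got {x.shape[-2:]}")
        f1 = self.pool(self.stage1(self.stem(x)))   # S/2
        f2 = self.pool(self.stage2(f1))             # S/4
        f3 = self.pool(self.stage3(f2))             # S/8
        f4 = self.pool(self.stage4(f3))             # S/16
        f5 = self.bottleneck_in(self.pool(f4))      # S/32
        self.encoder_scale_shapes_ = [f.shape for f in (f1, f2, f3, f4, f5)]
        d1 = self.dec1(self.gic(self.mdc(f5)))      # S/16
        d2 = self.dec2(d1)                          # S/8
        if self.bridges[2] is not None:
            d2 = d2 + self.bridges[2](f3)
        d3 = self.dec3(d2)                          # S/4
        if self.bridges[1] is not None:
            d3 = d3 + self.bridges[1](f2)
        d4 = self.dec4(d3)                          # S/2
        if self.bridges[0] is not None:
            d4 = d4 + self.bridges[0](f1)
        y = self.head_act(self.head_bn(self.head_up(d4)))
        return self.head(y)


def cross_entropy_loss(logits, target):
    """Softmax cross-entropy, Loss(x, c) = -x[c] + log sum_j exp(x[j]).

    Accepts either a single logit vector with an integer class (returns a
    float) or an (N, C, H, W) Tensor with (N, H, W) integer labels (returns
    the pixel-mean loss as a scalar Tensor for backprop).
    """
    if isinstance(logits, nn.Tensor):
        target = np.asarray(target)
        if target.min() < 0 or target.max() >= logits.shape[1]:
            raise ValueError("target labels outside the class range")
        return nn.softmax_cross_entropy(logits, target.astype(np.int64))
    x = np.asarray(logits, dtype=np.float64)
    c = int(target)
    if not 0 <= c < x.size:
        raise ValueError(f"target class {c} outside {{0..{x.size - 1}}}")
    m = x.max()
    return float(-x[c] + m + np.log(np.exp(x - m).sum()))


def save_checkpoint(net: RSAPNet, path) -> None:
    """Serialise weights + running statistics with the config as metadata."""
    arrays = {f"arr_{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, config=json.dumps(asdict(net.config)), **arrays)


def load_checkpoint(path) -> RSAPNet:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        for key in ("encoder_stage_channels", "mdc_dilations",
                    "gic_pool_sizes", "rsap_depths"):
            if cfg_dict.get(key) is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        cfg_dict["gic_conv_specs"] = tuple(
            tuple(p) for p in cfg_dict["gic_conv_specs"])
        net = RSAPNet(ModelConfig(**cfg_dict))
        for tgt, src in zip(net.state_arrays(),
                            (data[f"arr_{i}"]
                             for i in range(len(data.files) - 1))):
            tgt[...] = src
    return net
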