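"""MDWC-Net architecture: multi-scale adaptive-weighting encoder-decoder.

The network is a five-level encoder-decoder for binary segmentation of
grayscale radiographs.  Three bespoke blocks distinguish it from a plain
U-Net:

* **MSCAW** (multi-scale convolution adaptive weighting): four parallel
  depthwise-separable branches with kernels 1/3/5/7, each followed by batch
  norm, ReLU and a learnable per-channel scaling, concatenated along
  channels.
* **DFCB** (dual feature complementary block): skip fusion that gates both
  the encoder map and the reduced decoder map by a channel-softmax of the
  decoder map, then concatenates the two gated halves.
* **BIEB** (bottleneck information enhancement block): the sum of a
  channel-attention branch (avg+max pooling through a shared two-layer
  perceptron, sigmoid gate) and a residual double-convolution branch with
  adaptive weighting.

Every ablation variant (plain-conv blocks, plain concat skips, ASPP or CBAM
swap-ins, single BIEB branches) is reachable through ``NetworkConfig``.

The 3x3 convolutions inside BIEB are depthwise-separable: at the
1024-channel bottleneck, dense 3x3 convolutions alone would cost ~18.9M
parameters, an order of magnitude beyond the lightweight budget the design
targets, so the network's separable primitive is used there as everywhere
else.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidInputError


# ---------------------------------------------------------------------------
# Configuration


@dataclasses.dataclass
class NetworkConfig:
    """Architectural hyperparameters; defaults give the full MDWC-Net."""

    in_channels: int = 1
    num_classes: int = 2
    encoder_widths: tuple[int, ...] = (64, 128, 256, 512)
    kernel_set: tuple[int, ...] = (1, 3, 5, 7)
    mlp_reduction: int = 16
    use_mscaw_weighting: bool = True
    use_bieb_upper: bool = True
    use_bieb_lower: bool = True
    use_dfcb: bool = True
    skip_fusion: str = "dfcb"  # {dfcb, concat}
    bottleneck: str = "bieb"  # {bieb, plain, cbam}
    multiscale_block: str = "mscaw"  # {mscaw, plain_conv, aspp}
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        self.kernel_set = tuple(int(k) for k in self.kernel_set)
        self.validate()

    @property
    def bottleneck_width(self) -> int:
        # The widening block doubles the deepest encoder width, which is what
        # the 2C-channel contract of the DFCB skip fusion requires.
        return 2 * self.encoder_widths[-1]

    def validate(self) -> None:
        w = self.encoder_widths
        if len(w) < 2 or any(b <= a for a, b in zip(w, w[1:])):
            raise ConfigurationError(f"encoder widths must be strictly increasing, got {w}")
        if any(b != 2 * a for a, b in zip(w, w[1:])):
            # the skip-fusion channel contract (decoder carries 2C against an
            # encoder level's C) requires a doubling ladder
            raise ConfigurationError(f"encoder widths must double level to level, got {w}")
        nb = len(self.kernel_set)
        if nb < 1 or any(k % 2 == 0 or k < 1 for k in self.kernel_set):
            raise ConfigurationError(f"kernel set must contain odd sizes, got {self.kernel_set}")
        for width in w:
            if width % nb or width % 2:
                raise ConfigurationError(
                    f"every encoder width must be divisible by {nb} (branches) and by 2, got {width}"
                )
        if self.skip_fusion not in ("dfcb", "concat"):
            raise ConfigurationError(f"unknown skip_fusion {self.skip_fusion!r}")
        if self.bottleneck not in ("bieb", "plain", "cbam"):
            raise ConfigurationError(f"unknown bottleneck {self.bottleneck!r}")
        if self.multiscale_block not in ("mscaw", "plain_conv", "aspp"):
            raise ConfigurationError(f"unknown multiscale_block {self.multiscale_block!r}")
        if self.use_dfcb != (self.skip_fusion == "dfcb"):
            raise ConfigurationError("use_dfcb must agree with skip_fusion")
        if self.bottleneck == "bieb" and not (self.use_bieb_upper or self.use_bieb_lower):
            raise ConfigurationError("bottleneck='bieb' with both branches disabled")
        if self.mlp_reduction < 1 or self.mlp_reduction >= self.bottleneck_width:
            raise ConfigurationError(
                f"mlp_reduction {self.mlp_reduction} must be in [1, {self.bottleneck_width})"
            )
        if self.num_classes < 2 or self.in_channels < 1:
            raise ConfigurationError("need in_channels >= 1 and num_classes >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder_widths"] = list(self.encoder_widths)
        d["kernel_set"] = list(self.kernel_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


#: Table-style ablation presets, each reachable purely by configuration.
ABLATION_PRESETS: dict[str, dict] = {
    "baseline_unet": dict(multiscale_block="plain_conv", skip_fusion="concat",
                          use_dfcb=False, bottleneck="plain"),
    "multiscale_conv_only": dict(multiscale_block="mscaw", use_mscaw_weighting=False,
                                 skip_fusion="concat", use_dfcb=False, bottleneck="plain"),
    "mscaw_only": dict(multiscale_block="mscaw", skip_fusion="concat",
                       use_dfcb=False, bottleneck="plain"),
    "mscaw_bieb_upper": dict(skip_fusion="concat", use_dfcb=False, bottleneck="bieb",
                             use_bieb_upper=True, use_bieb_lower=False),
    "mscaw_bieb_lower": dict(skip_fusion="concat", use_dfcb=False, bottleneck="bieb",
                             use_bieb_upper=False, use_bieb_lower=True),
    "mscaw_bieb_full": dict(skip_fusion="concat", use_dfcb=False, bottleneck="bieb"),
    "mscaw_dfcb": dict(skip_fusion="dfcb", use_dfcb=True, bottleneck="plain"),
    "full": dict(),
    "with_aspp": dict(multiscale_block="aspp"),
    "with_cbam": dict(bottleneck="cbam"),
}


def ablation_config(name: str, **overrides) -> NetworkConfig:
    if name not in ABLATION_PRESETS:
        raise ConfigurationError(f"unknown ablation preset {name!r}; known: {sorted(ABLATION_PRESETS)}")
    kw = dict(ABLATION_PRESETS[name])
    kw.update(overrides)
    return NetworkConfig(**kw)


# ---------------------------------------------------------------------------
# Building blocks


class DepthwiseSeparableConv(nn.Layer):
    """Channel-wise k x k convolution followed by a 1x1 cross-channel mix.

    Bias-free on both stages (each conv is normalised downstream).
    """

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int):
        if kernel % 2 == 0:
            raise ConfigurationError(f"kernel size must be odd, got {kernel}")
        self.depthwise = nn.DepthwiseConv(rng, in_ch, kernel)
        self.pointwise = nn.PointwiseConv(rng, in_ch, out_ch)

    def children(self):
        return [self.depthwise, self.pointwise]

    def params(self):
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x, train=True):
        return self.pointwise.forward(self.depthwise.forward(x, train), train)

    def backward(self, grad):
        return self.depthwise.backward(self.pointwise.backward(grad))


class MSCAWBlock(nn.Layer):
    """Multi-scale convolution adaptive weighting block.

    Four parallel branches (kernel sizes from ``kernel_set``), each a
    depthwise-separable convolution to ``out_ch / n_branches`` channels,
    batch-normalised, ReLU-activated and scaled per channel by learnable
    adaptive weights (initialised at 1, trained by gradient descent).
    Branch outputs are concatenated along the channel axis.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, cfg: NetworkConfig):
        nb = len(cfg.kernel_set)
        if out_ch % nb:
            raise ConfigurationError(f"out_channels {out_ch} not divisible by {nb} branches")
        branch_ch = out_ch // nb
        self.branch_ch = branch_ch
        self.branches = []
        for k in cfg.kernel_set:
            layers = [
                DepthwiseSeparableConv(rng, in_ch, branch_ch, k),
                nn.BatchNorm2d(branch_ch, eps=cfg.bn_eps, momentum=cfg.bn_momentum),
                nn.ReLU(),
            ]
            if cfg.use_mscaw_weighting:
                layers.append(nn.AdaptiveChannelWeight(branch_ch))
            self.branches.append(nn.Sequential(*layers))

    def children(self):
        return list(self.branches)

    def params(self):
        out = []
        for b in self.branches:
            out.extend(b.params())
        return out

    def adaptive_weights(self) -> list[nn.Param]:
        out = []
        for b in self.branches:
            for layer in b.layers:
                if isinstance(layer, nn.AdaptiveChannelWeight):
                    out.append(layer.w)
        return out

    def forward(self, x, train=True):
        return np.concatenate([b.forward(x, train) for b in self.branches], axis=1)

    def backward(self, grad):
        c = self.branch_ch
        gx = None
        for i, b in enumerate(self.branches):
            g = b.backward(np.ascontiguousarray(grad[:, i * c : (i + 1) * c]))
            gx = g if gx is None else gx + g
        return gx


class PlainDoubleConv(nn.Layer):
    """Classic U-Net level block: two dense 3x3 conv + BN + ReLU stages."""

    def __init__(self, rng, in_ch: int, out_ch: int, cfg: NetworkConfig):
        self.seq = nn.Sequential(
            nn.Conv2d(rng, in_ch, out_ch, 3),
            nn.BatchNorm2d(out_ch, eps=cfg.bn_eps, momentum=cfg.bn_momentum),
            nn.ReLU(),
            nn.Conv2d(rng, out_ch, out_ch, 3),
            nn.BatchNorm2d(out_ch, eps=cfg.bn_eps, momentum=cfg.bn_momentum),
            nn.ReLU(),
        )

    def children(self):
        return [self.seq]

    def params(self):
        return self.seq.params()

    def forward(self, x, train=True):
        return self.seq.forward(x, train)

    def backward(self, grad):
        return self.seq.backward(grad)


class ASPPBlock(nn.Layer):
    """Minimal atrous spatial pyramid pooling drop-in (swap experiments).

    One 1x1 branch plus three 3x3 branches with dilation rates 1/2/3, each to
    ``out_ch / 4`` channels with BN + ReLU, concatenated.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, cfg: NetworkConfig):
        if out_ch % 4:
            raise ConfigurationError(f"ASPP needs out_channels divisible by 4, got {out_ch}")
        bc = out_ch // 4
        self.branch_ch = bc
        mk = lambda conv: nn.Sequential(conv, nn.BatchNorm2d(bc, eps=cfg.bn_eps,
                                                             momentum=cfg.bn_momentum), nn.ReLU())
        self.branches = [
            mk(nn.PointwiseConv(rng, in_ch, bc)),
            mk(nn.Conv2d(rng, in_ch, bc, 3, dilation=1)),
            mk(nn.Conv2d(rng, in_ch, bc, 3, dilation=2)),
            mk(nn.Conv2d(rng, in_ch, bc, 3, dilation=3)),
        ]

    def children(self):
        return list(self.branches)

    def params(self):
        out = []
        for b in self.branches:
            out.extend(b.params())
        return out

    def forward(self, x, train=True):
        return np.concatenate([b.forward(x, train) for b in self.branches], axis=1)

    def backward(self, grad):
        c = self.branch_ch
        gx = None
        for i, b in enumerate(self.branches):
            g = b.backward(np.ascontiguousarray(grad[:, i * c : (i + 1) * c]))
            gx = g if gx is None else gx + g
        return gx


def make_level_block(rng, in_ch: int, out_ch: int, cfg: NetworkConfig) -> nn.Layer:
    kind = cfg.multiscale_block
    if kind == "mscaw":
        return MSCAWBlock(rng, in_ch, out_ch, cfg)
    if kind == "plain_conv":
        return PlainDoubleConv(rng, in_ch, out_ch, cfg)
    return ASPPBlock(rng, in_ch, out_ch, cfg)


class DFCBBlock(nn.Layer):
    """Dual feature complementary skip fusion.

    Encoder path: 1x1 conv C -> C//2, BN, ReLU.  Decoder path: 1x1 conv
    2C -> C//2, then channel softmax.  The softmax map gates both paths by
    pixel-wise multiplication and the two gated halves are concatenated,
    restoring C channels.
    """

    def __init__(self, rng, enc_ch: int, cfg: NetworkConfig):
        if enc_ch < 2:
            raise ConfigurationError("DFCB needs at least 2 encoder channels")
        self.enc_ch = enc_ch
        half = enc_ch // 2
        self.enc_path = nn.Sequential(
            nn.PointwiseConv(rng, enc_ch, half),
            nn.BatchNorm2d(half, eps=cfg.bn_eps, momentum=cfg.bn_momentum),
            nn.ReLU(),
        )
        self.dec_conv = nn.PointwiseConv(rng, 2 * enc_ch, half)
        self.softmax = nn.ChannelSoftmax()

    def children(self):
        return [self.enc_path, self.dec_conv, self.softmax]

    def params(self):
        return self.enc_path.params() + self.dec_conv.params()

    def forward(self, enc, dec, train=True):
        if enc.shape[2:] != dec.shape[2:]:
            raise ConfigurationError(f"DFCB spatial mismatch: {enc.shape} vs {dec.shape}")
        if enc.shape[1] != self.enc_ch or dec.shape[1] != 2 * self.enc_ch:
            raise ConfigurationError(
                f"DFCB channel contract violated: enc {enc.shape[1]} (want {self.enc_ch}), "
                f"dec {dec.shape[1]} (want {2 * self.enc_ch})"
            )
        f_n1 = self.enc_path.forward(enc, train)
        f_i1 = self.dec_conv.forward(dec, train)
        f_i2 = self.softmax.forward(f_i1, train)
        self._f_n1, self._f_i1, self._f_i2 = f_n1, f_i1, f_i2
        f_nm = f_n1 * f_i2
        f_i3 = f_i1 * f_i2
        return np.concatenate([f_nm, f_i3], axis=1)

    def backward(self, grad):
        half = self.enc_ch // 2
        g_nm = grad[:, :half]
        g_i3 = grad[:, half:]
        f_n1, f_i1, f_i2 = self._f_n1, self._f_i1, self._f_i2
        g_n1 = g_nm * f_i2
        g_i2 = g_nm * f_n1 + g_i3 * f_i1
        g_i1 = g_i3 * f_i2 + self.softmax.backward(g_i2)
        g_enc = self.enc_path.backward(np.ascontiguousarray(g_n1))
        g_dec = self.dec_conv.backward(g_i1)
        return g_enc, g_dec


class ConcatFusion(nn.Layer):
    """Plain U-Net skip fusion: halve the upsampled decoder map with a 1x1
    conv and concatenate it after the encoder map (2C channels out)."""

    def __init__(self, rng, enc_ch: int):
        self.enc_ch = enc_ch
        self.halve = nn.PointwiseConv(rng, 2 * enc_ch, enc_ch)

    def children(self):
        return [self.halve]

    def params(self):
        return self.halve.params()

    def forward(self, enc, dec, train=True):
        if enc.shape[2:] != dec.shape[2:]:
            raise ConfigurationError(f"fusion spatial mismatch: {enc.shape} vs {dec.shape}")
        return np.concatenate([enc, self.halve.forward(dec, train)], axis=1)

    def backward(self, grad):
        c = self.enc_ch
        g_enc = np.ascontiguousarray(grad[:, :c])
        g_dec = self.halve.backward(np.ascontiguousarray(grad[:, c:]))
        return g_enc, g_dec


class BIEBChannelAttention(nn.Layer):
    """Upper BIEB branch: squeeze both global average- and max-pooled channel
    statistics through one shared two-layer perceptron, sum, sigmoid, and
    rescale the input channels by the resulting gate."""

    def __init__(self, rng, channels: int, mlp_reduction: int):
        if mlp_reduction >= channels:
            raise ConfigurationError(
                f"mlp_reduction {mlp_reduction} must be smaller than channel count {channels}"
            )
        hidden = max(channels // mlp_reduction, 1)
        self.channels = channels
        self.w1 = nn.Param(nn._he_init(rng, (hidden, channels), channels))
        self.b1 = nn.Param(np.zeros(hidden))
        self.w2 = nn.Param(nn._he_init(rng, (channels, hidden), hidden))
        self.b2 = nn.Param(np.zeros(channels))

    def children(self):
        return []

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def _mlp(self, p):
        h_pre = p @ self.w1.data.T + self.b1.data
        h = np.maximum(h_pre, 0)
        return h_pre, h, h @ self.w2.data.T + self.b2.data

    def gate(self, x, train=True):
        """The channel weight map zeta, shape (N, C), values in (0, 1)."""
        n, c, h, w = x.shape
        pa = x.mean(axis=(2, 3))
        xf = x.reshape(n, c, h * w)
        self._max_idx = xf.argmax(axis=-1)
        pm = np.take_along_axis(xf, self._max_idx[..., None], axis=-1)[..., 0]
        self._pa, self._pm = pa, pm
        self._a = self._mlp(pa)
        self._m = self._mlp(pm)
        z = 1.0 / (1.0 + np.exp(-(self._a[2] + self._m[2])))
        self._z = z.astype(nn.DTYPE)
        return self._z

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[2] < 1 or x.shape[3] < 1:
            raise ConfigurationError("channel attention needs a 4-D map with spatial size >= 1x1")
        z = self.gate(x, train)
        self._x = x
        return z[:, :, None, None] * x

    def _mlp_backward(self, cache, pooled, g_out):
        h_pre, h, _ = cache
        self.w2.grad += g_out.T @ h
        self.b2.grad += g_out.sum(axis=0)
        gh = (g_out @ self.w2.data) * (h_pre > 0)
        self.w1.grad += gh.T @ pooled
        self.b1.grad += gh.sum(axis=0)
        return gh @ self.w1.data

    def backward(self, grad):
        x, z = self._x, self._z
        n, c, h, w = x.shape
        gz = (grad * x).sum(axis=(2, 3))
        gx = z[:, :, None, None] * grad
        gs = gz * z * (1.0 - z)  # through the sigmoid; shared by both MLP paths
        g_pa = self._mlp_backward(self._a, self._pa, gs)
        g_pm = self._mlp_backward(self._m, self._pm, gs)
        gx += g_pa[:, :, None, None] / (h * w)
        gmax = np.zeros((n, c, h * w), dtype=nn.DTYPE)
        np.put_along_axis(gmax, self._max_idx[..., None], g_pm[..., None], axis=-1)
        gx += gmax.reshape(x.shape)
        return gx


class BIEBResidualBranch(nn.Layer):
    """Lower BIEB branch: two separable 3x3 conv/BN/ReLU stages stitched by
    residual additions, with adaptive channel weighting on the second stage."""

    def __init__(self, rng, channels: int, cfg: NetworkConfig):
        mk = lambda: nn.Sequential(
            DepthwiseSeparableConv(rng, channels, channels, 3),
            nn.BatchNorm2d(channels, eps=cfg.bn_eps, momentum=cfg.bn_momentum),
            nn.ReLU(),
        )
        self.stage1 = mk()
        self.stage2 = mk()
        self.delta = nn.AdaptiveChannelWeight(channels)

    def children(self):
        return [self.stage1, self.stage2, self.delta]

    def params(self):
        return self.stage1.params() + self.stage2.params() + self.delta.params()

    def forward(self, x, train=True):
        f5t = self.stage1.forward(x, train)
        f51 = f5t + x
        f52 = self.stage2.forward(f51, train)
        self.residual, self.weighted = f51, f52  # exposed for inspection
        return self.delta.forward(f52, train) + f51

    def backward(self, grad):
        g51 = grad + self.stage2.backward(self.delta.backward(grad))
        return g51 + self.stage1.backward(g51)


class BIEBBlock(nn.Layer):
    """Pixel-wise sum of the enabled channel-attention and residual branches."""

    def __init__(self, rng, channels: int, cfg: NetworkConfig):
        if not (cfg.use_bieb_upper or cfg.use_bieb_lower):
            raise ConfigurationError("BIEB with both branches disabled")
        self.upper = BIEBChannelAttention(rng, channels, cfg.mlp_reduction) if cfg.use_bieb_upper else None
        self.lower = BIEBResidualBranch(rng, channels, cfg) if cfg.use_bieb_lower else None

    def children(self):
        return [b for b in (self.upper, self.lower) if b is not None]

    def params(self):
        out = []
        for b in self.children():
            out.extend(b.params())
        return out

    def forward(self, x, train=True):
        y = None
        for b in self.children():
            z = b.forward(x, train)
            y = z if y is None else y + z
        return y

    def backward(self, grad):
        gx = None
        for b in self.children():
            g = b.backward(grad)
            gx = g if gx is None else gx + g
        return gx


class CBAMBlock(nn.Layer):
    """Minimal convolutional block attention drop-in: channel attention
    (shared-MLP avg+max squeeze) followed by 7x7 spatial attention."""

    def __init__(self, rng, channels: int, cfg: NetworkConfig):
        self.channel = BIEBChannelAttention(rng, channels, cfg.mlp_reduction)
        self.spatial_conv = nn.Conv2d(rng, 2, 1, 7, bias=True)

    def children(self):
        return [self.channel, self.spatial_conv]

    def params(self):
        return self.channel.params() + self.spatial_conv.params()

    def forward(self, x, train=True):
        xc = self.channel.forward(x, train)
        avg = xc.mean(axis=1, keepdims=True)
        mx_idx = xc.argmax(axis=1)
        mx = np.take_along_axis(xc, mx_idx[:, None], axis=1)
        s_pre = self.spatial_conv.forward(np.concatenate([avg, mx], axis=1), train)
        s = 1.0 / (1.0 + np.exp(-s_pre))
        self._xc, self._s, self._mx_idx = xc, s.astype(nn.DTYPE), mx_idx
        return s * xc

    def backward(self, grad):
        xc, s = self._xc, self._s
        gs = (grad * xc).sum(axis=1, keepdims=True) * s * (1.0 - s)
        g_cat = self.spatial_conv.backward(gs)
        g_xc = s * grad
        c = xc.shape[1]
        g_xc += g_cat[:, :1] / c
        g_mx = np.zeros_like(xc)
        np.put_along_axis(g_mx, self._mx_idx[:, None], g_cat[:, 1:2], axis=1)
        g_xc += g_mx
        return self.channel.backward(g_xc)


# ---------------------------------------------------------------------------
# Full network


class _DecoderLevel:
    def __init__(self, up, fuse, block):
        self.up, self.fuse, self.block = up, fuse, block


class MDWCNet:
    """Five-level encoder-decoder assembled from a :class:`NetworkConfig`.

    Encoder: one level block per width followed by 2x2 max-pooling (four
    pools).  Bottleneck: a widening level block to twice the deepest width,
    then the configured enhancement block (BIEB, CBAM, or none).  Decoder:
    bilinear 2x upsampling, skip fusion (DFCB or halve-and-concat), one level
    block per level.  A biased 1x1 convolution maps to class logits.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.encoder_widths
        self.enc_blocks = []
        self.pools = []
        cin = cfg.in_channels
        for width in w:
            self.enc_blocks.append(make_level_block(rng, cin, width, cfg))
            self.pools.append(nn.MaxPool2x2())
            cin = width
        self.widen = make_level_block(rng, w[-1], cfg.bottleneck_width, cfg)
        if cfg.bottleneck == "bieb":
            self.enhance = BIEBBlock(rng, cfg.bottleneck_width, cfg)
        elif cfg.bottleneck == "cbam":
            self.enhance = CBAMBlock(rng, cfg.bottleneck_width, cfg)
        else:
            self.enhance = None
        self.dec_levels = []
        for width in reversed(w):
            up = nn.UpsampleBilinear2x()
            if cfg.skip_fusion == "dfcb":
                fuse = DFCBBlock(rng, width, cfg)
                block = make_level_block(rng, width, width, cfg)
            else:
                fuse = ConcatFusion(rng, width)
                block = make_level_block(rng, 2 * width, width, cfg)
            self.dec_levels.append(_DecoderLevel(up, fuse, block))
        self.classifier = nn.PointwiseConv(rng, w[0], cfg.num_classes, bias=True)

    # -- traversal ---------------------------------------------------------

    def _layers(self):
        out = list(self.enc_blocks) + list(self.pools) + [self.widen]
        if self.enhance is not None:
            out.append(self.enhance)
        for lev in self.dec_levels:
            out.extend([lev.up, lev.fuse, lev.block])
        out.append(self.classifier)
        return out

    def params(self) -> list[nn.Param]:
        out = []
        for l in self._layers():
            out.extend(l.params())
        return out

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        found = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm2d):
                found.append(layer)
            kids = layer.children() if hasattr(layer, "children") else []
            if isinstance(layer, nn.Sequential):
                kids = layer.layers
            for k in kids:
                walk(k)

        for l in self._layers():
            walk(l)
        return found

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise InvalidInputError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        factor = 2 ** len(self.enc_blocks)
        if x.shape[2] % factor or x.shape[3] % factor:
            raise InvalidInputError(f"spatial dims must be divisible by {factor}, got {x.shape[2:]}")
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.widen.forward(h, train)
        if self.enhance is not None:
            h = self.enhance.forward(h, train)
        for i, lev in enumerate(self.dec_levels):
            h = lev.up.forward(h, train)
            enc = skips[-(i + 1)]
            h = lev.fuse.forward(enc, h, train)
            h = lev.block.forward(h, train)
        return self.classifier.forward(h, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.classifier.backward(grad)
        skip_grads = []
        for lev in reversed(self.dec_levels):
            g = lev.block.backward(g)
            g_enc, g = lev.fuse.backward(g)
            skip_grads.append(g_enc)
            g = lev.up.backward(g)
        skip_grads.reverse()  # now ordered deep -> shallow per encoder level
        if self.enhance is not None:
            g = self.enhance.backward(g)
        g = self.widen.backward(g)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[len(self.enc_blocks) - 1 - i]
            g = self.enc_blocks[i].backward(g)
        return g

    # -- checkpointing -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i:04d}": p.data for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i:04d}_mean"] = bn.running_mean
            state[f"bn_{i:04d}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = state[f"param_{i:04d}"]
            if arr.shape != p.data.shape:
                raise InvalidInputError(
                    f"checkpoint shape mismatch for param {i}: {arr.shape} vs {p.data.shape}"
                )
            p.data = np.ascontiguousarray(arr, dtype=nn.DTYPE)
            p.grad = np.zeros_like(p.data)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.ascontiguousarray(state[f"bn_{i:04d}_mean"], dtype=nn.DTYPE)
            bn.running_var = np.ascontiguousarray(state[f"bn_{i:04d}_var"], dtype=nn.DTYPE)


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> MDWCNet:
    """Construct the network; identical config + seed give identical weights."""
    return MDWCNet(cfg or NetworkConfig(), seed=seed)


def count_parameters(net: MDWCNet) -> int:
    """Exact number of trainable scalars (input-size invariant)."""
    return int(sum(p.data.size for p in net.params()))


def save_checkpoint(net: MDWCNet, path: str | Path) -> None:
    """Write weights (.npz) plus a sidecar .json with the producing config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_arrays())
    cfg_path = path.with_suffix(".json")
    cfg_path.write_text(json.dumps(net.cfg.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> MDWCNet:
    """Rebuild the network from a checkpoint without re-stating the config."""
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    cfg_path = path.with_suffix(".json")
    if not cfg_path.exists():
        raise InvalidInputError(f"missing sidecar config {cfg_path}")
    cfg = NetworkConfig.from_dict(json.loads(cfg_path.read_text()))
    net = build_network(cfg)
    with np.load(path) as state:
        net.load_state_arrays(dict(state))
    return net
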