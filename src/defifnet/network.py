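"""Full network assembly: dual encoder, bottleneck, skip CFRMs, RFE decoders.

Topology
--------
Each of the L encoder levels runs two streams in parallel: a U-Net style
branch of two 3x3 conv-BN-ReLU units capturing neighbouring dependencies, and
a global-dependency-fusion (GDF) branch whose single 7x7 convolution sees a
wide receptive field.  The streams are fused by elementwise addition followed
by a :class:`~defifnet.blocks.FIFConv`; the fused map feeds both the skip
connection (through a :class:`~defifnet.blocks.CFRM`) and — after 2x2 max
pooling — the next GDF level, while the U-Net branch propagates its own
pooled features.  After L levels the two streams are merged by addition and
pass through the bottleneck (two 3x3 conv-BN-ReLU units and an
:class:`~defifnet.blocks.MBGM`).  Each residual-feature-enhancement (RFE)
decoder level bilinearly upsamples the deep map, adjusts channels with a 1x1
convolution, concatenates the skip, reduces with two 3x3 conv-BN-ReLU units
to F1, and outputs FIFConv(F1) + F1.  A 1x1 head plus sigmoid (or softmax)
produces per-pixel probabilities.

The default channel schedule is fixed by the calibration search in
:mod:`defifnet.calibration` against the published budget of 0.24 M parameters
and 0.33 G MACs for a 3x256x256 input.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import CFRM, FIFConv, MBGM
from .nn import Conv2d, ConvBNReLU, Module

#: Channel schedule fixed by scripts/calibrate_channels.py against the
#: published parameter/MAC budget (see docs/methods.md).
DEFAULT_CHANNELS = (4, 4, 8, 44)
DEFAULT_BOTTLENECK = 44


class NumericError(RuntimeError):
    """Raised when activations become non-finite during a forward pass."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    depth:            number of encoder levels L (default 4)
    channels:         per-level widths c_1..c_L, all even and divisible by 4
    bottleneck_width: width of the bottleneck convolutions and MBGM
    input_size:       (H, W) the model is profiled at; H, W divisible by 2^L
    in_channels:      input image channels (3 for RGB)
    num_classes:      1 for binary masks (sigmoid head), >1 for softmax
    seed:             seed for weight initialization
    fif_norm_act:     add BN+ReLU inside FIFConv/CFRM convolutions
    """

    depth: int = 4
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    bottleneck_width: int = DEFAULT_BOTTLENECK
    input_size: tuple[int, int] = (256, 256)
    in_channels: int = 3
    num_classes: int = 1
    seed: int = 0
    fif_norm_act: bool = False

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        self.input_size = tuple(int(s) for s in self.input_size)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.channels) != self.depth:
            raise ValueError(
                f"channel schedule length {len(self.channels)} != depth {self.depth}")
        for c in self.channels:
            if c % 4:
                raise ValueError(
                    f"channel width {c} must be divisible by 4 (FIFConv/CFRM grouping)")
        for s in self.input_size:
            if s % (1 << self.depth):
                raise ValueError(
                    f"input size {self.input_size} not divisible by 2^{self.depth}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


class _EncoderLevel(Module):
    def __init__(self, left_in: int, gdf_in: int, out: int,
                 rng: np.random.Generator, fif_norm_act: bool):
        super().__init__()
        self.block1 = ConvBNReLU(left_in, out, 3, rng)
        self.block2 = ConvBNReLU(out, out, 3, rng)
        self.gdf_conv = Conv2d(gdf_in, out, 7, rng)
        self.fif = FIFConv(out, rng, norm_act=fif_norm_act)


class _DecoderLevel(Module):
    def __init__(self, deep: int, skip: int, rng: np.random.Generator,
                 fif_norm_act: bool):
        super().__init__()
        self.up_conv = Conv2d(deep, skip, 1, rng)
        self.conv1 = ConvBNReLU(2 * skip, skip, 3, rng)
        self.conv2 = ConvBNReLU(skip, skip, 3, rng)
        self.fif = FIFConv(skip, rng, norm_act=fif_norm_act)


class DEFIFNet(Module):
    """Dual-encoding feature interaction fusion segmentation network."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        cs = cfg.channels
        self.encoders = []
        left_in = gdf_in = cfg.in_channels
        for c in cs:
            self.encoders.append(_EncoderLevel(left_in, gdf_in, c, rng, cfg.fif_norm_act))
            left_in = gdf_in = c
        cb = cfg.bottleneck_width
        self.bottleneck1 = ConvBNReLU(cs[-1], cb, 3, rng)
        self.bottleneck2 = ConvBNReLU(cb, cb, 3, rng)
        self.mbgm = MBGM(cb, cb, cb, rng)
        self.cfrms = [CFRM(c, rng) for c in cs]
        self.decoders = []
        deep = cb
        for c in reversed(cs):
            self.decoders.append(_DecoderLevel(deep, c, rng, cfg.fif_norm_act))
            deep = c
        self.head = Conv2d(cs[0], cfg.num_classes, 1, rng)

    # -- level-wise pieces (also used directly by tests) -------------------
    def encoder_level(self, left_in: Tensor, gdf_in: Tensor, level: int
                      ) -> tuple[Tensor, Tensor]:
        """One dual-encoder level; returns (left_out, fused) pre-pooling."""
        enc = self.encoders[level]
        left_out = enc.block2(enc.block1(left_in))
        gdf_feat = enc.gdf_conv(gdf_in)
        fused = enc.fif(left_out + gdf_feat)
        return left_out, fused

    def decoder_level(self, deep: Tensor, skip: Tensor, level: int) -> Tensor:
        """One RFE decoder level (level indexes `self.decoders`, deepest first)."""
        dec = self.decoders[level]
        u = dec.up_conv(ad.upsample_bilinear2x(deep))
        if u.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"resolution mismatch after upsampling: {u.shape} vs {skip.shape}")
        f0 = ad.concat([u, skip])
        f1 = dec.conv2(dec.conv1(f0))
        return dec.fif(f1) + f1

    @staticmethod
    def _check_finite(t: Tensor, where: str) -> None:
        if not np.isfinite(t.data).all():
            raise NumericError(f"non-finite activations at {where}")

    def forward(self, image: Tensor | np.ndarray) -> Tensor:
        x = ad.as_tensor(image)
        cfg = self.config
        B, C, H, W = x.shape
        if C != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {C}")
        if H % (1 << cfg.depth) or W % (1 << cfg.depth):
            raise ValueError(
                f"spatial size ({H}, {W}) must be divisible by {1 << cfg.depth}")
        left = gdf = x
        skips: list[Tensor] = []
        for i in range(cfg.depth):
            left_out, fused = self.encoder_level(left, gdf, i)
            self._check_finite(fused, f"encoder level {i + 1}")
            skips.append(self.cfrms[i](fused))
            left = ad.max_pool2x2(left_out)
            gdf = ad.max_pool2x2(fused)
        merged = left + gdf
        deep = self.mbgm(self.bottleneck2(self.bottleneck1(merged)))
        self._check_finite(deep, "bottleneck")
        for j, skip in enumerate(reversed(skips)):
            deep = self.decoder_level(deep, skip, j)
            self._check_finite(deep, f"decoder level {cfg.depth - j}")
        logits = self.head(deep)
        if cfg.num_classes == 1:
            return ad.sigmoid(logits)
        return ad.softmax_channels(logits)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + all parameter/buffer arrays."""
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **state)

    @classmethod
    def load(cls, path) -> "DEFIFNet":
        with np.load(path) as data:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(data["__config__"].tobytes()).decode()))
            net = cls(cfg)
            net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return net


# ---------------------------------------------------------------------------
# Counters
# ---------------------------------------------------------------------------


def count_parameters(net: Module) -> int:
    """Exact number of trainable scalars (kernels, biases, BN/CFRM affines)."""
    return net.num_parameters()


def count_macs(net: DEFIFNet, input_size: tuple[int, int] | None = None) -> int:
    """Multiply-accumulate count of one forward pass at `input_size`.

    Convolutions contribute ``k^2 * C_in/groups * C_out * H_out * W_out``;
    every elementwise, pooling, normalization and resampling stage contributes
    one operation per output element.  The count is measured by instrumenting
    an actual forward pass, so it is additive over the graph by construction.
    """
    H, W = input_size or net.config.input_size
    was_training = net.training
    net.eval()
    x = np.zeros((1, net.config.in_channels, H, W), dtype=np.float32)
    with ad.counting_macs() as counter:
        net(x)
    net.train(was_training)
    return counter[0]


def summary(net: DEFIFNet, input_size: tuple[int, int] | None = None) -> dict:
    """Structured size/compute report (also rendered by `summary_text`)."""
    params = count_parameters(net)
    macs = count_macs(net, input_size)
    per_layer = []
    for name, child in net.children():
        per_layer.append({"layer": name, "parameters": child.num_parameters()})
    head_params = net.num_parameters() - sum(e["parameters"] for e in per_layer)
    if head_params:  # parameters registered directly on the root
        per_layer.append({"layer": "(root)", "parameters": head_params})
    return {
        "input_size": list(input_size or net.config.input_size),
        "parameters": params,
        "parameters_M": round(params / 1e6, 2),
        "macs": macs,
        "macs_G": round(macs / 1e9, 2),
        "per_layer": per_layer,
        "convention": (
            "convolutions: k^2*C_in/groups*C_out*H_out*W_out MACs; "
            "elementwise/pooling/normalization/resampling: 1 op per output element"
        ),
    }


def summary_text(net: DEFIFNet, input_size: tuple[int, int] | None = None) -> str:
    rep = summary(net, input_size)
    buf = io.StringIO()
    buf.write(f"input size: {rep['input_size'][0]}x{rep['input_size'][1]}\n")
    buf.write(f"{'layer':<24}{'parameters':>12}\n")
    for e in rep["per_layer"]:
        buf.write(f"{e['layer']:<24}{e['parameters']:>12}\n")
    buf.write(f"total parameters: {rep['parameters']} ({rep['parameters_M']:.2f} M)\n")
    buf.write(f"forward MACs:     {rep['macs']} ({rep['macs_G']:.2f} G)\n")
    buf.write(f"convention: {rep['convention']}\n")
    return buf.getvalue()
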