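"""Attention-enhanced dual-encoder segmentation network.

Two convolutional encoders run side by side on the same input: a deep
resnet50-style branch (bottleneck residual blocks) supplying semantic
features, and a lightweight mobilenetv2-style branch (inverted residual
blocks) supplying fine spatial detail. Each branch exposes four taps at
strides 2/4/8/16, projected by 1x1 convolutions to a fixed channel
contract (64/128/256/512 and 16/24/32/96 at the default width). Matching
levels are channel-concatenated; the deepest fused map (608 channels at
1/16 resolution for a 256 input) feeds a lightweight atrous spatial
pyramid pooling block — three depthwise-separable 3x3 branches at
dilations 1/6/12 plus a broadcast global-average-pool branch, concatenated
to 4x256 = 1024 channels. A four-stage decoder of 2x transposed
convolutions restores resolution, concatenating squeeze-and-excitation
gated fused skips at strides 8/4/2 (the final stage has no finer tap to
skip from), and a 1x1 convolution + sigmoid emits a per-pixel lesion
probability map the size of the input.

The ablation variant drops the mobilenet-style branch: skips are SE-gated
resnet taps and the block feeding the pyramid pooling is 512-channel.

Internal encoder widths are configurable; the printed tap/fusion/decoder
channel contract is enforced by the projection convolutions regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .datapipe import STANDARDIZATION
from .nn import functional as F
from .nn.tensor import Tensor, broadcast_spatial, concat, relu

logger = logging.getLogger(__name__)

RESNET_TAP_NAMES = ("conv2_block3_out", "conv3_block4_out",
                    "conv4_block6_out", "conv5_block3_out")
MOBILENET_TAP_NAMES = ("block_1_expand_relu", "block_3_expand_relu",
                       "block_6_expand_relu", "block_13_expand_relu")
TAP_STRIDES = (2, 4, 8, 16)


class ConfigurationError(ValueError):
    pass


@dataclass
class TapSpec:
    """Which layers of a backbone family are tapped, and at what width."""

    backbone_family: str                    # "resnet50-style" | "mobilenetv2-style"
    tap_names: tuple[str, ...]
    tap_channels: tuple[int, ...]
    tap_strides: tuple[int, ...] = TAP_STRIDES

    def __post_init__(self):
        if len(self.tap_names) != 4 or len(self.tap_channels) != 4:
            raise ConfigurationError("a tap spec needs exactly 4 taps")
        if list(self.tap_strides) != sorted(self.tap_strides) or \
                len(set(self.tap_strides)) != 4:
            raise ConfigurationError("tap strides must be strictly increasing")
        if any(c <= 0 for c in self.tap_channels):
            raise ConfigurationError("tap channels must be positive")


@dataclass
class FeaturePyramid:
    """Four feature maps at strides 2/4/8/16."""

    levels: list[Tensor]

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ConfigurationError("a feature pyramid has exactly 4 levels")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(lv.shape[1] for lv in self.levels)


@dataclass
class ModelConfig:
    input_size: int = 256
    resnet_tap_channels: tuple[int, ...] = (64, 128, 256, 512)
    mobilenet_tap_channels: tuple[int, ...] = (16, 24, 32, 96)
    fused_bottleneck_channels: int = 1024
    aspp_branch_channels: int = 256
    aspp_rates: tuple[int, ...] = (1, 6, 12)
    se_reduction: int = 16
    decoder_channels: tuple[int, ...] = (512, 256, 128, 64)
    pretrained_backbones: bool = False
    ablation_mode: bool = False
    # internal encoder widths (projections enforce the tap contract above)
    resnet_stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    resnet_blocks_per_stage: int = 2
    mobilenet_stage_widths: tuple[int, ...] = (16, 24, 32, 96)
    mobilenet_expansion: int = 4
    standardize_inputs: bool = True

    def __post_init__(self):
        problems = []
        if self.input_size % 16 != 0:
            problems.append(f"input_size {self.input_size} not divisible by 16")
        if len(self.aspp_rates) != 3:
            problems.append(f"aspp_rates must have 3 entries, got {self.aspp_rates}")
        if list(self.decoder_channels) != sorted(self.decoder_channels, reverse=True) \
                or len(set(self.decoder_channels)) != 4:
            problems.append(f"decoder_channels must be 4 strictly decreasing values,"
                            f" got {self.decoder_channels}")
        if self.fused_bottleneck_channels != 4 * self.aspp_branch_channels:
            problems.append(
                f"fused_bottleneck_channels {self.fused_bottleneck_channels} must be"
                f" 4 x aspp_branch_channels ({4 * self.aspp_branch_channels})")
        if self.pretrained_backbones:
            problems.append("pretrained_backbones is not available in this build;"
                            " only random initialization is implemented")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @classmethod
    def desk(cls, input_size: int = 64, *, ablation_mode: bool = False) -> "ModelConfig":
        """A narrow configuration sized for CPU-only training runs."""
        return cls(input_size=input_size,
                   resnet_tap_channels=(8, 12, 16, 24),
                   mobilenet_tap_channels=(4, 6, 8, 12),
                   fused_bottleneck_channels=64,
                   aspp_branch_channels=16,
                   se_reduction=4,
                   decoder_channels=(24, 16, 12, 8),
                   resnet_stage_widths=(16, 24, 32, 48),
                   resnet_blocks_per_stage=1,
                   mobilenet_stage_widths=(8, 12, 16, 24),
                   mobilenet_expansion=2,
                   ablation_mode=ablation_mode)

    def resnet_tap_spec(self) -> TapSpec:
        return TapSpec("resnet50-style", RESNET_TAP_NAMES, tuple(self.resnet_tap_channels))

    def mobilenet_tap_spec(self) -> TapSpec:
        return TapSpec("mobilenetv2-style", MOBILENET_TAP_NAMES,
                       tuple(self.mobilenet_tap_channels))

    def fused_channels(self) -> tuple[int, ...]:
        if self.ablation_mode:
            return tuple(self.resnet_tap_channels)
        return tuple(r + m for r, m in zip(self.resnet_tap_channels,
                                           self.mobilenet_tap_channels))

    def to_dict(self) -> dict:
        d = {}
        for k, v in vars(self).items():
            d[k] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# encoder building blocks

class ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, kernel, *, stride=1, dilation=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride=stride, dilation=dilation,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class BottleneckBlock(nn.Module):
    """1x1 reduce -> 3x3 -> 1x1 expand with an identity/projection skip."""

    def __init__(self, cin, cout, *, stride=1, rng=None):
        super().__init__()
        mid = max(4, cout // 4)
        self.reduce = ConvBNReLU(cin, mid, 1, rng=rng)
        self.spatial = ConvBNReLU(mid, mid, 3, stride=stride, rng=rng)
        self.expand = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.expand_bn = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = None

    def forward(self, x):
        y = self.expand_bn(self.expand(self.spatial(self.reduce(x))))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return relu(y + skip)


class InvertedResidualBlock(nn.Module):
    """1x1 expand -> depthwise 3x3 -> 1x1 linear project, residual when able."""

    def __init__(self, cin, cout, *, stride=1, expansion=4, rng=None):
        super().__init__()
        hidden = cin * expansion
        self.expand = ConvBNReLU(cin, hidden, 1, rng=rng)
        self.depthwise = nn.DepthwiseConv2d(hidden, 3, stride=stride, rng=rng)
        self.dw_bn = nn.BatchNorm2d(hidden)
        self.project = nn.Conv2d(hidden, cout, 1, bias=False, rng=rng)
        self.project_bn = nn.BatchNorm2d(cout)
        self.use_residual = stride == 1 and cin == cout

    def forward(self, x):
        y = self.expand(x)
        y = relu(self.dw_bn(self.depthwise(y)))
        y = self.project_bn(self.project(y))
        return y + x if self.use_residual else y


class ResNetStyleEncoder(nn.Module):
    """Bottleneck-residual encoder with taps at strides 2/4/8/16."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        w = config.resnet_stage_widths
        n = config.resnet_blocks_per_stage
        self.tap_spec = config.resnet_tap_spec()
        self.stem = ConvBNReLU(3, w[0], 7, stride=2, rng=rng)
        self.stages = []
        cin = w[0]
        for level, width in enumerate(w):
            blocks = []
            for b in range(n):
                stride = 2 if (level > 0 and b == 0) else 1
                blocks.append(BottleneckBlock(cin, width, stride=stride, rng=rng))
                cin = width
            self.stages.append(nn.Sequential(*blocks))
        self.projections = [nn.Conv2d(w[i], config.resnet_tap_channels[i], 1, rng=rng)
                            for i in range(4)]

    def forward(self, x) -> list[Tensor]:
        x = self.stem(x)
        taps = []
        for stage, proj in zip(self.stages, self.projections):
            x = stage(x)
            taps.append(proj(x))
        return taps


class MobileNetStyleEncoder(nn.Module):
    """Inverted-residual encoder with taps at strides 2/4/8/16."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        w = config.mobilenet_stage_widths
        e = config.mobilenet_expansion
        self.tap_spec = config.mobilenet_tap_spec()
        self.stem = ConvBNReLU(3, w[0], 3, stride=2, rng=rng)
        self.stages = []
        cin = w[0]
        for level, width in enumerate(w):
            blocks = [InvertedResidualBlock(cin, width,
                                            stride=(2 if level > 0 else 1),
                                            expansion=e, rng=rng)]
            cin = width
            self.stages.append(nn.Sequential(*blocks))
        self.projections = [nn.Conv2d(w[i], config.mobilenet_tap_channels[i], 1, rng=rng)
                            for i in range(4)]

    def forward(self, x) -> list[Tensor]:
        x = self.stem(x)
        taps = []
        for stage, proj in zip(self.stages, self.projections):
            x = stage(x)
            taps.append(proj(x))
        return taps


def extract_taps(encoder, image_batch) -> FeaturePyramid:
    """Run a headless encoder and return its projected multi-scale taps."""
    x = image_batch if isinstance(image_batch, Tensor) else Tensor(image_batch)
    if x.shape[2] % 16 or x.shape[3] % 16:
        raise ConfigurationError(
            f"input spatial size {x.shape[2:]} must be divisible by 16")
    return FeaturePyramid(encoder(x))


def align_and_fuse(pyr_a: FeaturePyramid, pyr_b: FeaturePyramid) -> FeaturePyramid:
    """Per level: resize b to a's spatial size (bilinear) and concatenate."""
    if len(pyr_a.levels) != len(pyr_b.levels):
        raise ConfigurationError("pyramids must have the same number of levels")
    fused = []
    for a, b in zip(pyr_a.levels, pyr_b.levels):
        b = F.resize_bilinear(b, a.shape[2], a.shape[3])
        fused.append(concat([a, b], axis=1))
    return FeaturePyramid(fused)


# ---------------------------------------------------------------------------
# attention / context / decoder

class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate:
    out = sigmoid(W2 ReLU(W1 GAP(X))) * X."""

    def __init__(self, channels: int, reduction: int = 16, *, rng=None):
        super().__init__()
        hidden = max(1, int(np.ceil(channels / reduction)))
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def gate(self, x) -> Tensor:
        n, c = x.shape[:2]
        squeezed = F.global_avg_pool(x).reshape(n, c)
        return nn.sigmoid(self.fc2(relu(self.fc1(squeezed)))).reshape(n, c, 1, 1)

    def forward(self, x):
        return x * self.gate(x)


def se_attention(x, reduction: int = 16, *, block: SEBlock | None = None,
                 rng=None) -> Tensor:
    """Functional SE gating (builds a fresh block unless one is supplied)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    block = block or SEBlock(x.shape[1], reduction, rng=rng)
    return block(x)


class ASPPLite(nn.Module):
    """Lightweight atrous spatial pyramid pooling: three depthwise-separable
    3x3 branches at dilations (1, 6, 12) plus a broadcast global-pool
    branch, each producing ``branch_channels``, concatenated."""

    def __init__(self, cin: int, branch_channels: int, rates=(1, 6, 12), *, rng=None):
        super().__init__()
        self.rates = tuple(rates)
        self.depthwise = [nn.DepthwiseConv2d(cin, 3, dilation=r, rng=rng)
                          for r in self.rates]
        self.pointwise = [ConvBNReLU(cin, branch_channels, 1, rng=rng)
                          for _ in self.rates]
        self.pool_proj = nn.Conv2d(cin, branch_channels, 1, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        branches = [pw(dw(x)) for dw, pw in zip(self.depthwise, self.pointwise)]
        pooled = relu(self.pool_proj(F.global_avg_pool(x)))
        branches.append(broadcast_spatial(pooled, h, w))
        return concat(branches, axis=1)


def lightweight_aspp(x, branch_channels: int, rates=(1, 6, 12), *,
                     module: ASPPLite | None = None, rng=None) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    module = module or ASPPLite(x.shape[1], branch_channels, rates, rng=rng)
    return module(x)


class DecoderStage(nn.Module):
    """Upsample x2 by transposed convolution, concatenate the SE-gated skip
    (when one exists at this scale), then refine with two 3x3 conv+BN+ReLU."""

    def __init__(self, cin_deep: int, skip_ch: int, cout: int, *,
                 se_reduction: int = 16, rng=None):
        super().__init__()
        self.skip_ch = skip_ch
        self.up = nn.ConvTranspose2x2(cin_deep, cout, rng=rng)
        self.se = SEBlock(skip_ch, se_reduction, rng=rng) if skip_ch else None
        self.refine1 = ConvBNReLU(cout + skip_ch, cout, 3, rng=rng)
        self.refine2 = ConvBNReLU(cout, cout, 3, rng=rng)

    def forward(self, deep, skip=None):
        if (skip is None) != (self.skip_ch == 0):
            raise ConfigurationError("decoder stage skip presence mismatch")
        y = self.up(deep)
        if skip is not None:
            if skip.shape[2] != 2 * deep.shape[2] or skip.shape[3] != 2 * deep.shape[3]:
                raise ConfigurationError(
                    f"skip spatial {skip.shape[2:]} must be 2x deep {deep.shape[2:]}")
            y = concat([y, self.se(skip)], axis=1)
        return self.refine2(self.refine1(y))


def decoder_stage(deep, skip, out_channels: int, *, se_reduction: int = 16,
                  rng=None) -> Tensor:
    """Functional form of one decoder stage with an SE-gated skip."""
    deep = deep if isinstance(deep, Tensor) else Tensor(deep)
    skip = skip if isinstance(skip, Tensor) else Tensor(skip)
    stage = DecoderStage(deep.shape[1], skip.shape[1], out_channels,
                         se_reduction=se_reduction, rng=rng)
    return stage(deep, skip)


# ---------------------------------------------------------------------------
# full network

class DualEncoderSegNet(nn.Module):
    """End-to-end segmentation network; see the module docstring."""

    def __init__(self, config: ModelConfig, *, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        self.resnet = ResNetStyleEncoder(config, rng)
        self.mobilenet = None if config.ablation_mode else MobileNetStyleEncoder(config, rng)
        fused = config.fused_channels()
        self.aspp = ASPPLite(fused[3], config.aspp_branch_channels,
                             config.aspp_rates, rng=rng)
        dch = config.decoder_channels
        aspp_out = 4 * config.aspp_branch_channels
        self.decoder_stages = [
            DecoderStage(aspp_out, fused[2], dch[0], se_reduction=config.se_reduction, rng=rng),
            DecoderStage(dch[0], fused[1], dch[1], se_reduction=config.se_reduction, rng=rng),
            DecoderStage(dch[1], fused[0], dch[2], se_reduction=config.se_reduction, rng=rng),
            DecoderStage(dch[2], 0, dch[3], se_reduction=config.se_reduction, rng=rng),
        ]
        self.head = nn.Conv2d(dch[3], 1, 1, rng=rng)
        self.activations: dict[str, Tensor] = {}
        self._std_const = {
            fam: (np.asarray(m, dtype=np.float32).reshape(1, 3, 1, 1),
                  np.asarray(s, dtype=np.float32).reshape(1, 3, 1, 1))
            for fam, (m, s) in STANDARDIZATION.items()}

    # -- plumbing ----------------------------------------------------------
    def _standardized(self, x: Tensor, family: str) -> Tensor:
        if not self.config.standardize_inputs:
            return x
        mean, std = self._std_const[family]
        return (x * 255.0 - Tensor(mean)) * Tensor(1.0 / std)

    def activation(self, layer_id: str) -> Tensor:
        aliases = dict(zip(RESNET_TAP_NAMES,
                           [f"resnet_tap{i}" for i in range(1, 5)]))
        aliases.update(zip(MOBILENET_TAP_NAMES,
                           [f"mobilenet_tap{i}" for i in range(1, 5)]))
        key = aliases.get(layer_id, layer_id)
        if key not in self.activations:
            raise ConfigurationError(
                f"unknown layer {layer_id!r}; available: {sorted(self.activations)}")
        return self.activations[key]

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[1] != 3:
            raise ConfigurationError(f"expected NCHW RGB input, got {x.shape}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ConfigurationError(
                f"input spatial size {x.shape[2:]} must be divisible by 16")
        acts = self.activations = {}
        r_taps = self.resnet(self._standardized(x, "resnet-branch"))
        for i, t in enumerate(r_taps, 1):
            acts[f"resnet_tap{i}"] = t
        if self.mobilenet is not None:
            m_taps = self.mobilenet(self._standardized(x, "mobilenet-branch"))
            for i, t in enumerate(m_taps, 1):
                acts[f"mobilenet_tap{i}"] = t
            fused = align_and_fuse(FeaturePyramid(r_taps),
                                   FeaturePyramid(m_taps)).levels
        else:
            fused = r_taps
        for i, t in enumerate(fused, 1):
            acts[f"fused{i}"] = t
        y = self.aspp(fused[3])
        acts["aspp"] = y
        skips = [fused[2], fused[1], fused[0], None]
        for i, (stage, skip) in enumerate(zip(self.decoder_stages, skips), 1):
            y = stage(y, skip)
            acts[f"decoder{i}"] = y
        out = nn.sigmoid(self.head(y))
        acts["output"] = out
        return out

    # -- inference convenience ----------------------------------------------
    def predict(self, images: np.ndarray, *, batch_size: int = 4) -> np.ndarray:
        """Probability maps for (N, H, W, 3) images in [0, 1] -> (N, H, W)."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        was_training = self.training
        self.eval()
        outs = []
        with nn.no_grad():
            for i in range(0, len(images), batch_size):
                batch = images[i:i + batch_size].transpose(0, 3, 1, 2)
                outs.append(self.forward(batch).data[:, 0])
        self.train(was_training)
        return np.concatenate(outs, axis=0)


def assemble_model(config: ModelConfig | None = None, seed: int = 0
                   ) -> DualEncoderSegNet:
    """Build the full dual-encoder network with seeded initialization."""
    config = config or ModelConfig()
    if config.ablation_mode:
        raise ConfigurationError("use assemble_ablation for ablation_mode configs")
    model = DualEncoderSegNet(config, rng=np.random.default_rng(seed))
    logger.info("assembled dual-encoder model: %d parameters", model.num_parameters())
    return model


def assemble_ablation(config: ModelConfig | None = None, seed: int = 0
                      ) -> DualEncoderSegNet:
    """Build the resnet-only ablation variant (no fusion branch)."""
    if config is None:
        config = ModelConfig(ablation_mode=True)
    if not config.ablation_mode:
        raise ConfigurationError("assemble_ablation requires ablation_mode=True")
    model = DualEncoderSegNet(config, rng=np.random.default_rng(seed))
    logger.info("assembled ablation model: %d parameters", model.num_parameters())
    return model


def save_checkpoint(model: DualEncoderSegNet, path) -> None:
    """Serialize weights + config with numpy's archive format."""
    from pathlib import Path
    import json
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> DualEncoderSegNet:
    import json
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    config = ModelConfig.from_dict(
        json.loads(bytes(state.pop("__config__")).decode()))
    model = DualEncoderSegNet(config, rng=np.random.default_rng(0))
    model.load_state_dict(state)
    return model
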