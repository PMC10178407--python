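"""Encoder–decoder wound segmentation network.

The encoder is a short-term dense concatenate (STDC) backbone: six stages, of
which stages 1–2 are single ConvX units and stages 3–5 are chains of STDC
blocks whose first block halves the spatial resolution.  An STDC block runs a
short chain of ConvX units with geometrically shrinking channel widths
(N/2, N/4, N/8, N/8) and concatenates every intermediate output, yielding
multi-receptive-field features at a fixed channel budget N.

The decoder follows the BiSeNet context-path recipe: globally pooled context,
attention-refine modules (channel gates) on the two deepest stages, stepwise
bilinear upsampling, and a feature-fusion module joining the 1/8-resolution
encoder feature with the decoder counterpart.  Coordinate attention —
direction-aware gates built from separate row and column pooling — is applied
before and after the fusion when enabled.

Two capacity variants are exposed, named 813 and 1446 after the backbone
family they instantiate: (2,2,2) and (4,5,3) STDC blocks in stages 3–5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    SGD,  # noqa: F401  (re-exported for callers that build training loops)
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    ConvX,
    Linear,
    Module,
    Sequential,
    Tensor,
    bilinear_matrix,
    concat,
    upsample_bilinear,
)

DEFAULT_BLOCKS = {813: (2, 2, 2), 1446: (4, 5, 3)}


class ConfigError(ValueError):
    """Invalid network configuration."""


@dataclass
class NetworkConfig:
    """Architecture description; fully determines the built network."""

    variant: int = 813
    use_coordinate_attention: bool = True
    num_classes: int = 2
    input_side: int = 512
    stage_channels: tuple[int, ...] = (32, 64, 256, 512, 1024)
    blocks_per_stage: tuple[int, int, int] | None = None
    ca_reduction: int = 32
    decoder_channels: int | None = None
    ffm_channels: int | None = None
    arm_on_stage3: bool = False
    include_classifier: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.variant not in DEFAULT_BLOCKS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected 813 or 1446")
        if self.input_side % 32 != 0 or self.input_side <= 0:
            raise ConfigError("input_side must be a positive multiple of 32")
        if self.num_classes < 1:
            raise ConfigError("num_classes must be positive")
        ch = tuple(self.stage_channels)
        if len(ch) != 5 or any(c <= 0 for c in ch):
            raise ConfigError("stage_channels must be 5 positive integers")
        if any(a >= b for a, b in zip(ch, ch[1:])):
            raise ConfigError("stage_channels must be strictly increasing")
        if any(c % 8 for c in ch[2:]):
            raise ConfigError("stage 3-5 channels must be divisible by 8 (STDC plan)")
        self.stage_channels = ch
        if self.blocks_per_stage is None:
            self.blocks_per_stage = DEFAULT_BLOCKS[self.variant]
        self.blocks_per_stage = tuple(self.blocks_per_stage)
        if len(self.blocks_per_stage) != 3 or any(b < 1 for b in self.blocks_per_stage):
            raise ConfigError("blocks_per_stage must be 3 positive integers")
        if self.ca_reduction < 1:
            raise ConfigError("ca_reduction must be >= 1")
        if self.decoder_channels is None:
            self.decoder_channels = max(8, ch[2] // 2)
        if self.ffm_channels is None:
            self.ffm_channels = ch[2]


class STDCBlock(Module):
    """Short-term dense concatenate block.

    A chain of ``n_convx`` ConvX units emitting N/2, N/4, ..., N/2^(n-1),
    N/2^(n-1) channels; all intermediate outputs are concatenated, so the
    block emits exactly N channels.  With stride 2 the stride is applied in
    the second ConvX and the first chain output is average-pooled (3x3,
    stride 2) so every concatenated part shares the halved spatial grid.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, n_convx: int = 4):
        super().__init__()
        if n_convx < 2:
            raise ConfigError("STDC block needs at least 2 ConvX units")
        if out_ch % (2 ** (n_convx - 1)):
            raise ConfigError(
                f"STDC out_channels {out_ch} must be divisible by {2 ** (n_convx - 1)}"
            )
        if stride not in (1, 2):
            raise ConfigError("STDC stride must be 1 or 2")
        self.stride = stride
        plan = [out_ch // (2 ** (i + 1)) for i in range(n_convx - 1)]
        plan.append(plan[-1])  # the tail repeats the smallest width
        self.plan = plan
        units = []
        prev = in_ch
        for i, width in enumerate(plan):
            k = 1 if i == 0 else 3
            s = stride if i == 1 else 1
            units.append(ConvX(prev, width, kernel=k, stride=s))
            prev = width
        self.units = units
        self.skip_pool = AvgPool2d(3, 2, 1) if stride == 2 else None

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        for i, unit in enumerate(self.units):
            x = unit(x)
            outs.append(x)
        if self.skip_pool is not None:
            outs[0] = self.skip_pool(outs[0])
        return concat(outs, axis=1)


class CoordinateAttention(Module):
    """Direction-aware attention: pool along rows and columns separately,
    transform jointly through a reduced bottleneck, and emit per-(channel,row)
    and per-(channel,column) sigmoid gates multiplied into the input."""

    def __init__(self, channels: int, reduction: int = 32):
        super().__init__()
        if reduction > channels:
            raise ConfigError(
                f"coordinate-attention reduction {reduction} exceeds channel count {channels}"
            )
        mid = max(4, channels // reduction)
        self.reduce = ConvX(channels, mid, kernel=1)
        self.to_h = Conv2d(mid, channels, kernel=1, padding=0)
        self.to_w = Conv2d(mid, channels, kernel=1, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        xh = x.mean(axis=3, keepdims=True)                    # (B,C,H,1)
        xw = x.mean(axis=2, keepdims=True).permute(0, 1, 3, 2)  # (B,C,W,1)
        joint = self.reduce(concat([xh, xw], axis=2))         # (B,mid,H+W,1)
        jh = joint.slice((slice(None), slice(None), slice(0, H), slice(None)))
        jw = joint.slice((slice(None), slice(None), slice(H, H + W), slice(None)))
        gate_h = self.to_h(jh).sigmoid()                      # (B,C,H,1)
        gate_w = self.to_w(jw).sigmoid().permute(0, 1, 3, 2)  # (B,C,1,W)
        return x * gate_h * gate_w


class AttentionRefine(Module):
    """Channel gate from globally pooled features (shape preserving)."""

    def __init__(self, channels: int):
        super().__init__()
        self.conv = Conv2d(channels, channels, kernel=1, padding=0, bias=False)
        self.bn = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3), keepdims=True)
        gate = self.bn(self.conv(pooled)).sigmoid()
        return x * gate


class FeatureFusion(Module):
    """Concatenate low- and high-level features, project with a ConvX, and
    apply a channel-attention residual (pooled gate, multiply, add)."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.project = ConvX(in_ch, out_ch, kernel=1)
        self.squeeze = Conv2d(out_ch, max(4, out_ch // 4), kernel=1, padding=0)
        self.excite = Conv2d(max(4, out_ch // 4), out_ch, kernel=1, padding=0)

    def forward(self, low: Tensor, high: Tensor) -> Tensor:
        if low.shape[2:] != high.shape[2:]:
            raise ValueError(
                f"feature_fusion spatial mismatch: {low.shape[2:]} vs {high.shape[2:]}"
            )
        feat = self.project(concat([low, high], axis=1))
        gate = self.excite(self.squeeze(feat.mean(axis=(2, 3), keepdims=True)).relu()).sigmoid()
        return feat * gate + feat


class SegHead(Module):
    def __init__(self, in_ch: int, mid_ch: int, out_ch: int):
        super().__init__()
        self.conv = ConvX(in_ch, mid_ch, kernel=3)
        self.out = Conv2d(mid_ch, out_ch, kernel=1, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.conv(x))


class SegmentationNetwork(Module):
    """The full encoder–decoder; built by :func:`build_network`."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        ch = config.stage_channels
        dec = config.decoder_channels
        blocks = config.blocks_per_stage

        self.stage1 = ConvX(3, ch[0], kernel=3, stride=2)
        self.stage2 = ConvX(ch[0], ch[1], kernel=3, stride=2)
        self.stage3 = self._make_stage(ch[1], ch[2], blocks[0])
        self.stage4 = self._make_stage(ch[2], ch[3], blocks[1])
        self.stage5 = self._make_stage(ch[3], ch[4], blocks[2])

        # context path (decoder)
        self.global_context = ConvX(ch[4], dec, kernel=1)
        self.arm5 = AttentionRefine(ch[4])
        self.arm4 = AttentionRefine(ch[3])
        self.arm3 = AttentionRefine(ch[2]) if config.arm_on_stage3 else None
        self.compress5 = ConvX(ch[4], dec, kernel=1)
        self.compress4 = ConvX(ch[3], dec, kernel=1)
        self.refine5 = ConvX(dec, dec, kernel=3)
        self.refine4 = ConvX(dec, dec, kernel=3)

        if config.use_coordinate_attention:
            self.ca_pre = CoordinateAttention(dec, config.ca_reduction)
            self.ca_post = CoordinateAttention(config.ffm_channels, config.ca_reduction)
        else:
            self.ca_pre = None
            self.ca_post = None

        self.ffm = FeatureFusion(ch[2] + dec, config.ffm_channels)
        self.head = SegHead(config.ffm_channels, dec, config.num_classes)
        self.aux_head4 = SegHead(ch[3], dec, config.num_classes)
        self.aux_head5 = SegHead(ch[4], dec, config.num_classes)
        self.detail_head = SegHead(ch[2], dec, 1)

        if config.include_classifier:
            self.cls_conv = ConvX(ch[4], ch[4], kernel=1)
            self.cls_fc1 = Linear(ch[4], ch[4])
            self.cls_fc2 = Linear(ch[4], config.num_classes)

        self.reset_parameters(np.random.default_rng(config.seed))

    @staticmethod
    def _make_stage(in_ch: int, out_ch: int, n_blocks: int) -> Sequential:
        layers = [STDCBlock(in_ch, out_ch, stride=2)]
        layers += [STDCBlock(out_ch, out_ch, stride=1) for _ in range(n_blocks - 1)]
        return Sequential(*layers)

    # -- forward passes -------------------------------------------------------
    def encode(self, x: Tensor) -> list[Tensor]:
        feats = []
        for stage in (self.stage1, self.stage2, self.stage3, self.stage4, self.stage5):
            x = stage(x)
            feats.append(x)
        return feats

    def forward_full(self, x: Tensor) -> dict[str, Tensor]:
        """All heads; used for training.  Input is (B,3,S,S) with S=input_side."""
        s1, s2, s3, s4, s5 = self.encode(x)
        if self.arm3 is not None:
            s3 = self.arm3(s3)
        ctx = self.global_context(s5.mean(axis=(2, 3), keepdims=True))
        f5 = self.compress5(self.arm5(s5)) + ctx
        f5 = self.refine5(upsample_bilinear(f5, s4.shape[2:]))
        f4 = self.compress4(self.arm4(s4)) + f5
        f4 = self.refine4(upsample_bilinear(f4, s3.shape[2:]))
        if self.ca_pre is not None:
            f4 = self.ca_pre(f4)
        fused = self.ffm(s3, f4)
        if self.ca_post is not None:
            fused = self.ca_post(fused)
        logits = upsample_bilinear(self.head(fused), x.shape[2:])
        return {
            "logits": logits,
            "aux4": self.aux_head4(s4),
            "aux5": self.aux_head5(s5),
            "detail": self.detail_head(s3),
        }

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_full(x)["logits"]

    def classify(self, x: Tensor) -> Tensor:
        """Backbone-classification tail: ConvX, global average pooling, two
        fully connected layers.  Only available when the config enables it."""
        if not self.config.include_classifier:
            raise RuntimeError("network was built without the classification tail")
        *_, s5 = self.encode(x)
        pooled = self.cls_conv(s5).mean(axis=(2, 3))
        return self.cls_fc2(self.cls_fc1(pooled).relu())


def build_network(config: NetworkConfig) -> SegmentationNetwork:
    """Build the segmentation network described by ``config``.

    Initial parameters are drawn from a generator seeded with ``config.seed``,
    so two builds with the same config are bit-identical.
    """
    return SegmentationNetwork(config)


# -- whole-image inference -----------------------------------------------------

_NORM_MEAN, _NORM_STD = 0.5, 0.25


def _resize_float(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an (H,W) or (H,W,C) float array."""
    H2, W2 = size
    Ah = bilinear_matrix(H2, arr.shape[0], dtype=np.float64)
    Aw = bilinear_matrix(W2, arr.shape[1], dtype=np.float64)
    if arr.ndim == 2:
        return Ah @ arr @ Aw.T
    return np.einsum("oh,hwc,pw->opc", Ah, arr, Aw, optimize=True)


def segment_image(network: SegmentationNetwork, image: np.ndarray) -> np.ndarray:
    """Run the network on an RGB image of arbitrary resolution.

    The image is resized to the configured square working resolution, class
    scores are normalised to probabilities, and the wound-class probability
    map is resized back to the native resolution.  Returns (H, W) floats in
    [0, 1].
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    H, W = img.shape[:2]
    if H < 32 or W < 32:
        raise ValueError("image smaller than 32 px per side")
    side = network.config.input_side
    x = _resize_float(img.astype(np.float64) / 255.0, (side, side))
    x = (x - _NORM_MEAN) / _NORM_STD
    x = x.transpose(2, 0, 1)[None].astype(np.float32)
    network.eval()
    logits = network.forward(Tensor(x))
    probs = logits.softmax(axis=1).data[0]
    wound_class = min(1, network.config.num_classes - 1)
    prob = probs[wound_class]
    out = _resize_float(prob.astype(np.float64), (H, W))
    return np.clip(out, 0.0, 1.0)


# -- checkpoints ---------------------------------------------------------------


def save_checkpoint(network: SegmentationNetwork, path: str) -> None:
    """Serialise config + parameters to one file; parameter round-trip is
    bit-exact."""
    cfg = asdict(network.config)
    state = network.state_dict()
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
                 **state)


def load_checkpoint(path: str) -> SegmentationNetwork:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    for key in ("stage_channels", "blocks_per_stage"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    net = build_network(NetworkConfig(**cfg))
    net.load_state_dict(state)
    return net
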