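"""U-net generator with dilated-residual blocks, channel attention and
multi-scale information fusion.

The generator maps a zero-filled (aliased) magnitude image to a de-aliased
reconstruction.  Each encoder level stacks three dilated residual (DR) blocks
with dilation rates (1, 2, 3) — the second convolution of each block is
dilated, enlarging the receptive field without adding parameters — followed
by a channel attention module that reweights channels from combined global
max- and average-pooled statistics.  The decoder mirrors the encoder with
corner-aligned bilinear upsampling and skip-connection concatenation; a
multi-scale fusion head aggregates decoder features from every resolution.
The network predicts a residual correction added to its input, so a
zero-initialised head is exactly the identity map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, concat, global_avg_pool, global_max_pool,
                       upsample_bilinear)
from .nn import BatchNorm2d, Conv2d, Linear, MaxPool2d, Module, Sequential

__all__ = ["DRBlockConfig", "GeneratorConfig", "DRBlock", "ChannelAttention",
           "MultiScaleFusion", "Generator"]


@dataclass
class DRBlockConfig:
    channels: int
    dilation_rate: int = 1
    kernel_size: int = 3

    def __post_init__(self):
        if self.dilation_rate not in (1, 2, 3):
            raise ValueError("dilation_rate must be 1, 2 or 3")


@dataclass
class GeneratorConfig:
    depth: int = 4
    base_channels: int = 32
    dilation_rates: tuple[int, ...] = (1, 2, 3)
    use_cam: bool = True
    use_fusion: bool = True
    use_dilation: bool = True
    use_global_residual: bool = True
    cam_reduction: int = 8
    cam_combine: str = "sum"  # or "concat"

    def effective_dilations(self) -> tuple[int, ...]:
        """Per-level DR-block dilation rates; all 1 when dilation is ablated."""
        if self.use_dilation:
            return tuple(self.dilation_rates)
        return tuple(1 for _ in self.dilation_rates)


class DRBlock(Module):
    """Residual unit whose second convolution is dilated.

    conv3x3 -> BN -> ReLU -> conv3x3(dilation r, padding r) -> BN
    -> + identity -> ReLU.  Shape-preserving; parameter count is independent
    of the dilation rate.
    """

    def __init__(self, cfg: DRBlockConfig, rng: np.random.Generator):
        super().__init__()
        c, k = cfg.channels, cfg.kernel_size
        self.cfg = cfg
        self.conv1 = Conv2d(c, c, k, rng=rng)
        self.bn1 = BatchNorm2d(c)
        self.conv2 = Conv2d(c, c, k, dilation=cfg.dilation_rate, rng=rng)
        self.bn2 = BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + x).relu()


class ChannelAttention(Module):
    """Channel reweighting from combined global max and average pooling.

    Each channel's global max-pooled and average-pooled statistics pass
    through a two-layer bottleneck MLP whose weights are shared across
    channels (hidden width ``max(1, C // reduction)``); the two paths are
    summed (or the two statistics concatenated before the MLP, per config)
    and squashed by a logistic function into per-channel weights in (0, 1)
    that scale the input channel-wise.  Sharing the transform across channels
    makes the attention exactly permutation-equivariant: channels with
    identical content receive identical weights.
    """

    def __init__(self, channels: int, reduction: int = 8, combine: str = "sum",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if combine not in ("sum", "concat"):
            raise ValueError("combine must be 'sum' or 'concat'")
        if channels < reduction:
            warnings.warn(
                f"channels ({channels}) < reduction ({reduction}); "
                "clamping bottleneck width to 1", stacklevel=2)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.combine = combine
        in_features = 2 if combine == "concat" else 1
        self.fc1 = Linear(in_features, hidden, rng=rng)
        self.fc2 = Linear(hidden, 1, rng=rng)

    def _transform(self, pooled: Tensor) -> Tensor:
        """Shared bottleneck applied channelwise to (N, C, k) statistics."""
        n, c, k = pooled.shape
        flat = pooled.reshape(n * c, k)
        return self.fc2(self.fc1(flat).relu()).reshape(n, c)

    def channel_weights(self, x: Tensor) -> Tensor:
        if x.shape[1] < 2:
            raise ValueError("channel attention needs at least 2 channels")
        n, c = x.shape[0], x.shape[1]
        avg = global_avg_pool(x).reshape(n, c, 1)
        mx = global_max_pool(x).reshape(n, c, 1)
        if self.combine == "concat":
            logits = self._transform(concat([avg, mx], axis=2))
        else:
            logits = self._transform(avg) + self._transform(mx)
        return logits.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        w = self.channel_weights(x)
        return x * w.reshape(n, c, 1, 1)


class MultiScaleFusion(Module):
    """Aggregate decoder features from all resolutions at full resolution.

    Each level is projected to a common width by a 1x1 convolution, bilinearly
    upsampled to the finest grid, summed, and fused by one 3x3 convolution.
    """

    def __init__(self, in_channels: list[int], out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.projections = [Conv2d(c, out_channels, 1, rng=rng)
                            for c in in_channels]
        self.fuse = Conv2d(out_channels, out_channels, 3, rng=rng)

    def forward(self, features: list[Tensor]) -> Tensor:
        if not features:
            raise ValueError("fusion needs at least one feature map")
        if len(features) != len(self.projections):
            raise ValueError(
                f"expected {len(self.projections)} levels, got {len(features)}")
        n = features[0].shape[0]
        if any(f.shape[0] != n for f in features):
            raise ValueError("inconsistent batch size across fusion levels")
        h = max(f.shape[2] for f in features)
        w = max(f.shape[3] for f in features)
        total = None
        for proj, f in zip(self.projections, features):
            g = proj(f)
            if g.shape[2] != h or g.shape[3] != w:
                g = upsample_bilinear(g, h, w)
            total = g if total is None else total + g
        return self.fuse(total.relu())


class Generator(Module):
    """The full encoder/decoder reconstruction network."""

    def __init__(self, cfg: GeneratorConfig | None = None, in_channels: int = 1,
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or GeneratorConfig()
        rng = np.random.default_rng(seed)
        d = cfg.depth
        chans = [cfg.base_channels * 2**l for l in range(d)]
        self.channels = chans
        rates = cfg.effective_dilations()

        self.pool = MaxPool2d(2)
        self.in_conv = Conv2d(in_channels, chans[0], 3, rng=rng)
        self.enc_convs = []   # channel-lifting conv per level > 0
        self.enc_blocks = []  # three DR blocks per level
        self.enc_cams = []
        for l in range(d):
            if l > 0:
                self.enc_convs.append(Conv2d(chans[l - 1], chans[l], 3, rng=rng))
            self.enc_blocks.append(Sequential(
                *[DRBlock(DRBlockConfig(chans[l], r), rng) for r in rates]))
            if cfg.use_cam:
                self.enc_cams.append(ChannelAttention(
                    chans[l], cfg.cam_reduction, cfg.cam_combine, rng))

        self.dec_up_convs = []    # after upsample: chans[l+1] -> chans[l]
        self.dec_merge_convs = [] # after skip concat: 2*chans[l] -> chans[l]
        for l in range(d - 2, -1, -1):
            self.dec_up_convs.append(Conv2d(chans[l + 1], chans[l], 3, rng=rng))
            self.dec_merge_convs.append(Conv2d(2 * chans[l], chans[l], 3, rng=rng))

        head_in = chans[0]
        if cfg.use_fusion:
            # decoder emits levels deep-to-shallow: bottleneck first
            fusion_channels = [chans[d - 1]] + chans[:d - 1][::-1]
            self.fusion = MultiScaleFusion(fusion_channels, chans[0], rng)
        self.head = Conv2d(head_in, in_channels, 1, zero_init=True)

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.cfg.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by {div} "
                f"(depth {self.cfg.depth})")

        # encoder
        skips = []
        feat = x
        for l in range(self.cfg.depth):
            if l == 0:
                feat = self.in_conv(feat).relu()
            else:
                feat = self.pool(feat)
                feat = self.enc_convs[l - 1](feat).relu()
            feat = self.enc_blocks[l](feat)
            if self.cfg.use_cam:
                feat = self.enc_cams[l](feat)
            skips.append(feat)

        # decoder with skip concatenation; collect per-scale outputs
        multiscale = [skips[-1]]  # bottleneck, coarsest
        feat = skips[-1]
        for i, l in enumerate(range(self.cfg.depth - 2, -1, -1)):
            feat = upsample_bilinear(feat, skips[l].shape[2], skips[l].shape[3])
            feat = self.dec_up_convs[i](feat).relu()
            feat = concat([feat, skips[l]], axis=1)
            feat = self.dec_merge_convs[i](feat).relu()
            multiscale.append(feat)

        if self.cfg.use_fusion:
            feat = self.fusion(multiscale)
        residual = self.head(feat)
        if self.cfg.use_global_residual:
            return x + residual
        return residual

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        """Inference on a (N, H, W) stack of zero-filled magnitude images."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(np.asarray(images)[:, None])).data[:, 0]
        finally:
            self.train(was_training)
        return out
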