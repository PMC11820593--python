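"""The dual-channel fusion classifier: 1-D ResNet-ICBAM + 2-D CNN.

Channel attention (over a (B, C, L) feature map F):

    F_avg = mean_L F,  F_max = max_L F                    (per channel)
    W_c   = sigmoid(FC2(ReLU(FC1(F_avg + F_max))))
    F1    = F * W_c + F                                   (residual add)

Spatial attention takes F1, pools across channels (max and mean),
concatenates the two 1 x L maps, convolves them to a single map, puts
it through a sigmoid, multiplies into F1 and re-adds the *module
input* F — reusing the backbone's global features is what
distinguishes this "improved CBAM" (ICBAM) from plain CBAM.

The 1-D branch is an 18-layer-style ResNet with halved stage widths
(32, 64, 128, 256) whose residual blocks insert ICBAM before their
second convolution; the 2-D branch is a plain three-convolution CNN
over the 100 x 100 x 3 GADF/MTF/RP image. The two feature vectors
(256 and 144 wide) are concatenated to 400, passed through dropout, a
400 -> 200 ReLU layer, and a 200 -> 5 softmax classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import (
    AdaptiveMaxPool2d,
    BatchNorm1d,
    Conv1d,
    Conv2d,
    Dropout,
    Linear,
    MaxPool1d,
    MaxPool2d,
    Module,
    Tensor,
    concat,
)

__all__ = [
    "ICBAMConfig",
    "FusionNetConfig",
    "ChannelAttention",
    "SpatialAttention",
    "ICBAM",
    "ICBAMResidualBlock",
    "ResNetICBAMBranch",
    "Conv2DBranch",
    "FusionNet",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class ICBAMConfig:
    """Attention hyper-parameters for a block with ``channels`` maps."""

    channels: int
    reduction_ratio: int = 4
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if self.channels % self.reduction_ratio:
            raise ValueError("channels must be divisible by reduction_ratio")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")


@dataclass(frozen=True)
class FusionNetConfig:
    """Architecture hyper-parameters of the fusion network.

    The defaults realize the published layer table exactly: a 1800-point
    segment through stage widths (32, 64, 128, 256) to a 256-feature
    vector, a 100 x 100 x 3 image through (64, 32, 16) 2-D convolutions
    to 144 features, fused to 400 -> 200 -> 5. Smaller configurations
    (shorter input, smaller image, narrower stages) are legal and used
    for fast training runs.
    """

    input_len: int = 1800
    image_size: int = 100
    stem_channels: int = 64
    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    conv2d_channels: tuple[int, int, int] = (64, 32, 16)
    hidden_dim: int = 200
    n_classes: int = 5
    dropout: float = 0.5
    reduction_ratio: int = 4
    spatial_kernel: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        h = self.image_size - 6          # conv 7x7 valid
        h = (h - 3) // 3 + 1             # maxpool 3x3 stride 3
        h = h - 4                        # conv 5x5 valid
        h = (h - 3) // 3 + 1 if h >= 3 else 0
        h = h - 2                        # conv 3x3 valid
        if h < 1:
            raise ValueError(
                f"image_size={self.image_size} too small for the 2-D conv "
                "chain (needs >= 45)"
            )
        if self.input_len < 16:
            raise ValueError("input_len too short for the 1-D branch")

    @property
    def feat1_dim(self) -> int:
        return self.stage_channels[-1]

    @property
    def feat2_dim(self) -> int:
        # after three valid convs (7, 5, 3), two 3x3/3 maxpools and an
        # adaptive 3x3 max pool: channels * 9
        return self.conv2d_channels[-1] * 9

    @property
    def fused_dim(self) -> int:
        return self.feat1_dim + self.feat2_dim

    @classmethod
    def small(cls, seed: int = 0) -> "FusionNetConfig":
        """A scaled-down network for fast CPU training."""
        return cls(
            input_len=360,
            image_size=48,
            stem_channels=8,
            stage_channels=(8, 8, 16, 16),
            conv2d_channels=(8, 8, 8),
            hidden_dim=32,
            reduction_ratio=4,
            seed=seed,
        )


class ChannelAttention(Module):
    """Per-channel gating with a residual add (F1 = F * W_c + F)."""

    def __init__(self, cfg: ICBAMConfig, rng: np.random.Generator):
        super().__init__()
        hidden = cfg.channels // cfg.reduction_ratio
        self.fc1 = Linear(cfg.channels, hidden, rng)
        self.fc2 = Linear(hidden, cfg.channels, rng)

    def weights(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=2) + x.amax(axis=2)  # (B, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        w = self.weights(x).reshape(b, c, 1)
        return x * w + x


class SpatialAttention(Module):
    """Per-position gating; re-adds the ICBAM module input."""

    def __init__(self, cfg: ICBAMConfig, rng: np.random.Generator):
        super().__init__()
        k = cfg.spatial_kernel
        self.conv = Conv1d(2, 1, k, rng, stride=1, pad=(k - 1) // 2)

    def weights(self, f1: Tensor) -> Tensor:
        mx = f1.amax(axis=1, keepdims=True)  # (B, 1, L)
        mean = f1.mean(axis=1, keepdims=True)
        return self.conv(concat([mx, mean], axis=1)).sigmoid()

    def forward(self, f1: Tensor, module_input: Tensor) -> Tensor:
        return f1 * self.weights(f1) + module_input


class ICBAM(Module):
    """Improved convolutional block attention: channel then spatial,
    each with a residual re-add of the backbone features.

    ``bypass=True`` turns the module into the identity, which reduces
    the surrounding network to a plain ResNet.
    """

    def __init__(self, cfg: ICBAMConfig, rng: np.random.Generator, bypass: bool = False):
        super().__init__()
        self.bypass = bypass
        self.channel = ChannelAttention(cfg, rng)
        self.spatial = SpatialAttention(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.bypass:
            return x
        f1 = self.channel(x)
        return self.spatial(f1, x)


class ICBAMResidualBlock(Module):
    """conv3-BN-ReLU -> ICBAM -> conv3-BN -> (+ shortcut) -> ReLU.

    The second BatchNorm's scale starts at zero so a freshly
    initialized block is the identity plus shortcut. When stride or
    channel count changes, the shortcut is a 1 x 1 projection with BN.
    ``L_out = floor((L_in + 2 - 3) / stride) + 1``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int,
        rng: np.random.Generator,
        reduction_ratio: int = 4,
        spatial_kernel: int = 7,
        attention_bypass: bool = False,
    ):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.conv1 = Conv1d(in_channels, out_channels, 3, rng, stride=stride, pad=1)
        self.bn1 = BatchNorm1d(out_channels)
        self.icbam = ICBAM(
            ICBAMConfig(out_channels, reduction_ratio, spatial_kernel),
            rng,
            bypass=attention_bypass,
        )
        self.conv2 = Conv1d(out_channels, out_channels, 3, rng, stride=1, pad=1)
        self.bn2 = BatchNorm1d(out_channels)
        self.bn2.gamma.data[:] = 0.0  # residual branch starts silent
        self.project = in_channels != out_channels or stride != 1
        if self.project:
            self.short_conv = Conv1d(
                in_channels, out_channels, 1, rng, stride=stride, pad=0, bias=False
            )
            self.short_bn = BatchNorm1d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.icbam(out)
        out = self.bn2(self.conv2(out))
        shortcut = self.short_bn(self.short_conv(x)) if self.project else x
        return (out + shortcut).relu()


class ResNetICBAMBranch(Module):
    """1-D branch: stem conv + maxpool, four ICBAM residual stages,
    adaptive average pooling to one value per channel."""

    def __init__(self, cfg: FusionNetConfig, rng: np.random.Generator,
                 attention_bypass: bool = False):
        super().__init__()
        self.cfg = cfg
        self.stem = Conv1d(1, cfg.stem_channels, 7, rng, stride=2, pad=3)
        self.stem_bn = BatchNorm1d(cfg.stem_channels)
        self.pool = MaxPool1d(3, 2, pad=1)
        strides = (1, 2, 2, 2)
        chans = [cfg.stem_channels, *cfg.stage_channels]
        self.stages = [
            ICBAMResidualBlock(
                chans[i], chans[i + 1], strides[i], rng,
                cfg.reduction_ratio, cfg.spatial_kernel, attention_bypass,
            )
            for i in range(4)
        ]

    def forward(self, x: Tensor, trace: list | None = None) -> Tensor:
        def note(name: str, t: Tensor) -> None:
            if trace is not None:
                trace.append((name, t.shape[1:]))

        note("Input1", x)
        out = self.stem(x)
        note("Conv1d Module", out)
        out = self.stem_bn(out).relu()
        note("Batch Normalization Module", out)
        out = self.pool(out)
        note("MaxPooling1d", out)
        for i, stage in enumerate(self.stages, start=1):
            out = stage(out)
            note(f"ICBAM Residuals Module{i}", out)
        out = out.mean(axis=2, keepdims=True)
        note("AdaptiveAvgPool1d", out)
        out = out.reshape(out.shape[0], -1)
        if trace is not None:
            trace.append(("Flatten1", (out.shape[1],)))
        return out


class Conv2DBranch(Module):
    """2-D branch over the stacked GADF/MTF/RP image (ReLU after each
    conv, valid padding, per the published layer table)."""

    def __init__(self, cfg: FusionNetConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3 = cfg.conv2d_channels
        self.conv1 = Conv2d(3, c1, 7, rng)
        self.pool1 = MaxPool2d(3, 3)
        self.conv2 = Conv2d(c1, c2, 5, rng)
        self.pool2 = MaxPool2d(3, 3)
        self.conv3 = Conv2d(c2, c3, 3, rng)
        self.adaptive = AdaptiveMaxPool2d((3, 3))

    def forward(self, x: Tensor, trace: list | None = None) -> Tensor:
        def note(name: str, t: Tensor) -> None:
            if trace is not None:
                # report HWC like the layer table
                b, c, h, w = t.shape
                trace.append((name, (h, w, c)))

        note("Input2", x)
        out = self.conv1(x).relu()
        note("Conv2d Module1", out)
        out = self.pool1(out)
        note("MaxPooling2d1", out)
        out = self.conv2(out).relu()
        note("Conv2d Module2", out)
        out = self.pool2(out)
        note("MaxPooling2d2", out)
        out = self.conv3(out).relu()
        note("Conv2d Module3", out)
        out = self.adaptive(out)
        note("AdaptiveMaxPool2d", out)
        out = out.reshape(out.shape[0], -1)
        if trace is not None:
            trace.append(("Flatten2", (out.shape[1],)))
        return out


class FusionNet(Module):
    """Dual-channel fusion classifier.

    ``forward`` takes segments of shape (B, input_len) and images of
    shape (B, image_size, image_size, 3) (HWC, 8-bit or float) and
    returns logits (B, n_classes); ``predict_proba`` applies softmax.
    """

    def __init__(self, cfg: FusionNetConfig | None = None,
                 attention_bypass: bool = False):
        super().__init__()
        self.cfg = cfg = cfg or FusionNetConfig()
        rng = np.random.default_rng(cfg.seed)
        self.branch1 = ResNetICBAMBranch(cfg, rng, attention_bypass)
        self.branch2 = Conv2DBranch(cfg, rng)
        self.drop = Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 1))
        self.fc1 = Linear(cfg.fused_dim, cfg.hidden_dim, rng)
        self.fc2 = Linear(cfg.hidden_dim, cfg.n_classes, rng)

    @staticmethod
    def _prep(segments: np.ndarray, images: np.ndarray) -> tuple[Tensor, Tensor]:
        seg = np.asarray(segments, dtype=np.float64)
        if seg.ndim == 2:
            seg = seg[:, None, :]
        img = np.asarray(images, dtype=np.float64)
        if img.dtype != np.float64 or img.max() > 1.5:
            img = img / 255.0
        img = np.transpose(img, (0, 3, 1, 2))  # HWC -> CHW
        return Tensor(seg), Tensor(img)

    def forward(
        self,
        segments: np.ndarray | Tensor,
        images: np.ndarray | Tensor,
        trace: list | None = None,
    ) -> Tensor:
        if not isinstance(segments, Tensor):
            segments, images = self._prep(segments, np.asarray(images))
        x1 = self.branch1(segments, trace)
        x2 = self.branch2(images, trace)
        fused = concat([x1, x2], axis=1)
        if trace is not None:
            trace.append(("Concatenate", (fused.shape[1],)))
        fused = self.drop(fused)
        if trace is not None:
            trace.append(("Droupout", (fused.shape[1],)))
        hidden = self.fc1(fused).relu()
        if trace is not None:
            trace.append(("Dense(ReLU)", (hidden.shape[1],)))
        logits = self.fc2(hidden)
        if trace is not None:
            trace.append(("Softmax", (logits.shape[1],)))
        return logits

    def predict_proba(self, segments: np.ndarray, images: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(segments, images)
        finally:
            self.train(was_training)
        return softmax(logits.data)

    def shape_audit(self) -> dict[str, tuple[int, ...]]:
        """Walk a probe batch through the network and report every
        layer's output size (channels-first for the 1-D branch, HWC for
        the 2-D branch, scalars for the head)."""
        was_training = self.training
        self.eval()
        try:
            trace: list = []
            seg = np.zeros((2, self.cfg.input_len))
            img = np.zeros((2, self.cfg.image_size, self.cfg.image_size, 3))
            self.forward(seg, img, trace=trace)
        finally:
            self.train(was_training)
        out: dict[str, tuple[int, ...]] = {}
        for name, shape in trace:
            out[name] = tuple(int(s) for s in shape)
        return out
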