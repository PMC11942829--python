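"""The four denoising architectures: DnCNN, UDnCNN, DUDnCNN and AttnGAN.

All three DnCNN variants share one eight-convolution backbone (first conv +
ReLU, six conv+BN+ReLU blocks, final conv back to the image channels, all
3x3 with 64 filters and size-preserving padding):

* **DnCNN** runs the backbone as-is — no pooling anywhere, so fine detail
  is never resampled.
* **UDnCNN** bends the backbone into a U: 2x2 max pooling (storing argmax
  indices) after selected contraction convs, index-based 2x2 unpooling at
  the mirrored expansion convs, and skip features merged by elementwise
  ``(up + skip) / 2``.
* **DUDnCNN** keeps the exact UDnCNN parameterisation but replaces each
  pool/unpool with an increase/decrease of the convolution dilation
  (``dilation = 2**(poolings - unpoolings)``), trading resolution loss for
  receptive-field growth at zero extra parameters.

The **AttnGAN** pairs a U-shaped generator whose stages are gated by CBAM
(channel-then-spatial attention) with a patch-level discriminator that maps
a 256x256 input to a 30x30 score map.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import numpy as np
import yaml

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "NetworkConfig", "dilation_for_layer", "dilation_schedule",
    "DnCNN", "UDnCNN", "DUDnCNN", "CBAM", "AttnUNet", "PixelDiscriminator",
    "build_model", "build_discriminator", "denoise",
    "conv_output_size", "save_checkpoint", "load_checkpoint",
]

_FAMILIES = ("dncnn", "udncnn", "dudncnn", "attngan")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters shared by the model builders.

    ``pool_positions`` lists the (1-based) backbone conv layers after which
    a 2x2 pooling stage (or its dilation replacement) occurs; unpooling
    happens after the mirrored layers ``depth - i``.  The default single
    input/output channel matches scintigraphy; ``channels=3`` reproduces an
    RGB-replicated compatibility mode.
    """
    family: str = "dncnn"
    depth: int = 8
    filters: int = 64
    kernel: int = 3
    in_channels: int = 1
    out_channels: int = 1
    pool_positions: Tuple[int, ...] = (2, 3)
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family '{self.family}'; choose from {_FAMILIES}")
        if self.depth < 3:
            raise ValueError("depth must be at least 3")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        for i in self.pool_positions:
            if not (1 <= i < self.depth - 1) or (self.depth - i) <= i:
                raise ValueError(
                    "pool positions must sit in the contraction half so every "
                    "pooling has a mirrored unpooling")

    @property
    def unpool_positions(self) -> Tuple[int, ...]:
        return tuple(self.depth - i for i in self.pool_positions)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["pool_positions"] = list(d["pool_positions"])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text)
        d["pool_positions"] = tuple(d.get("pool_positions", (2, 3)))
        return cls(**d)


def dilation_for_layer(kappa: int, iota: int) -> int:
    """Dilation of a conv layer given poolings (kappa) and unpoolings (iota)
    completed so far: ``2**(kappa - iota)``, i.e. 1 when balanced and 2 after
    a single pooling replacement."""
    if iota > kappa or kappa < 0 or iota < 0:
        raise ValueError("require kappa >= iota >= 0")
    return 2 ** (kappa - iota)


def dilation_schedule(config: NetworkConfig) -> Tuple[int, ...]:
    """Per-backbone-layer dilation factors implied by the pool positions."""
    dils = []
    for layer in range(1, config.depth + 1):
        kappa = sum(1 for p in config.pool_positions if p < layer)
        iota = sum(1 for u in config.unpool_positions if u < layer)
        dils.append(dilation_for_layer(kappa, iota))
    return tuple(dils)


def conv_output_size(size: int, kernel: int, stride: int = 1,
                     padding: int = 0, dilation: int = 1) -> int:
    """Spatial output side of a convolution (the standard floor formula)."""
    span = dilation * (kernel - 1) + 1
    return (size + 2 * padding - span) // stride + 1


class _DnCNNBase(nn.Module):
    """Shared 8-conv backbone; subclasses decide pooling/dilation placement."""

    def __init__(self, config: NetworkConfig, dilations: Optional[Tuple[int, ...]] = None):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
        d = config.depth
        fs = config.filters
        k = config.kernel
        dilations = dilations or (1,) * d
        self.dilations = dilations
        self.convs = []
        self.bns = []
        for layer in range(1, d + 1):
            cin = config.in_channels if layer == 1 else fs
            cout = config.out_channels if layer == d else fs
            dil = dilations[layer - 1]
            pad = dil * (k - 1) // 2       # size-preserving for any dilation
            self.convs.append(nn.Conv2d(cin, cout, k, padding=pad,
                                        dilation=dil, rng=rng))
            # batch norm on the middle layers only (not first, not last)
            self.bns.append(nn.BatchNorm2d(cout) if 1 < layer < d else None)

    @property
    def n_conv_layers(self) -> int:
        return len(self.convs)

    def _block(self, x: Tensor, layer: int) -> Tensor:
        """Conv layer ``layer`` (1-based) with its BN/ReLU where present."""
        x = self.convs[layer - 1](x)
        bn = self.bns[layer - 1]
        if bn is not None:
            x = bn(x)
        if layer < self.config.depth:
            x = x.relu()
        return x


class DnCNN(_DnCNNBase):
    """Plain denoiser: no pooling, spatial size preserved end to end."""

    def forward(self, x: Tensor) -> Tensor:
        for layer in range(1, self.config.depth + 1):
            x = self._block(x, layer)
        return x


class UDnCNN(_DnCNNBase):
    """U-shaped variant: index-storing max pooling and mirrored unpooling."""

    def forward(self, x: Tensor) -> Tensor:
        levels = len(self.config.pool_positions)
        side = x.shape[1]
        if side % (2 ** levels):
            raise ValueError(
                f"input side {side} not divisible by 2^{levels} pooling stages")
        stack = []                       # (indices, skip, (H, W))
        unpool_at = set(self.config.unpool_positions)
        pool_at = set(self.config.pool_positions)
        for layer in range(1, self.config.depth + 1):
            x = self._block(x, layer)
            if layer in pool_at:
                size = x.shape[1:3]
                pooled, idx = F.max_pool2d(x, 2)
                stack.append((idx, x, size))
                x = pooled
            if layer in unpool_at:
                idx, skip, size = stack.pop()
                x = (F.max_unpool2d(x, idx, size) + skip) / 2.0
        return x


class DUDnCNN(_DnCNNBase):
    """Dilated variant: same parameters as UDnCNN, constant spatial size."""

    def __init__(self, config: NetworkConfig):
        super().__init__(config, dilations=dilation_schedule(config))

    def forward(self, x: Tensor) -> Tensor:
        for layer in range(1, self.config.depth + 1):
            x = self._block(x, layer)
        return x


class CBAM(nn.Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel attention runs a shared two-layer MLP over the global average-
    and max-pooled descriptors and gates channels through a sigmoid; spatial
    attention convolves the channel-wise mean and max maps with a 7x7 kernel
    into a sigmoid mask.
    """

    def __init__(self, channels: int, reduction: int = 8, spatial_kernel: int = 7,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.spatial = nn.Conv2d(2, 1, spatial_kernel,
                                 padding=spatial_kernel // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[-1]
        avg = F.spatial_mean(x).reshape(n, c)
        mx = F.spatial_max(x).reshape(n, c)
        gate_c = (self.fc2(self.fc1(avg).relu())
                  + self.fc2(self.fc1(mx).relu())).sigmoid().reshape(n, 1, 1, c)
        x = x * gate_c
        stats = F.concat([F.channel_mean(x), F.channel_max(x)], axis=-1)
        gate_s = self.spatial(stats).sigmoid()
        return x * gate_s


class _DownStage(nn.Module):
    """conv(+BN+ReLU) doubling depth, 2x2 max pool, CBAM."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.cbam = CBAM(cout, rng=rng)

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        y = self.bn(self.conv(x)).relu()
        pooled, _ = F.max_pool2d(y, 2)
        return self.cbam(pooled), y        # (downsampled, pre-pool skip)


class _UpStage(nn.Module):
    """transposed conv, skip concat, conv(+BN+ReLU) halving depth, CBAM."""

    def __init__(self, cin: int, skip_channels: int, cout: int,
                 rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, kernel=2, stride=2, rng=rng)
        self.conv = nn.Conv2d(cout + skip_channels, cout, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.cbam = CBAM(cout, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.up(x)
        x = F.concat([x, skip], axis=-1)
        x = self.bn(self.conv(x)).relu()
        return self.cbam(x)


class AttnUNet(nn.Module):
    """Attention-gated U-shaped generator (four down/up stages, CBAM gates).

    Feature depth doubles from ``filters`` at each of the four downsampling
    steps (64 -> 128 -> 256 -> 512 -> 1024 at the bottleneck by default) and
    halves on the way back up; the final 3x3 conv restores the image
    channels.  Inputs must be divisible by 16 per side.
    """

    def __init__(self, config: NetworkConfig, stages: int = 4):
        super().__init__()
        self.config = config
        self.stages = stages
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6A9]))
        f = config.filters
        self.stem = nn.Conv2d(config.in_channels, f, 3, padding=1, rng=rng)
        self.stem_bn = nn.BatchNorm2d(f)
        downs, chans = [], f
        for _ in range(stages):
            downs.append(_DownStage(chans, chans * 2, rng))
            chans *= 2
        self.downs = downs
        ups = []
        for _ in range(stages):
            ups.append(_UpStage(chans, chans, chans // 2, rng))
            chans //= 2
        self.ups = ups
        self.head = nn.Conv2d(chans, config.out_channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        side = x.shape[1]
        if side % (2 ** self.stages):
            raise ValueError(
                f"input side {side} must be divisible by {2 ** self.stages}")
        x = self.stem_bn(self.stem(x)).relu()
        skips = []
        for down in self.downs:
            x, skip = down(x)
            skips.append(skip)
        for up, skip in zip(self.ups, reversed(skips)):
            x = up(x, skip)
        return self.head(x)


class PixelDiscriminator(nn.Module):
    """Patch-level critic: strided conv stack to a score map (256 -> 30).

    Four 4x4 convolutions with increasing depth (strides 2, 2, 2, 1) and a
    final 4x4 conv to one channel; each interior score summarises a local
    receptive field rather than the whole image, so the output is a 30x30
    patch map for a 256x256 input.
    """

    _PLAN = ((64, 2), (128, 2), (256, 2), (512, 1))   # (depth, stride)

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD15C]))
        layers = []
        cin = config.in_channels
        for i, (depth, stride) in enumerate(self._PLAN):
            layers.append(nn.Conv2d(cin, depth, 4, stride=stride, padding=1, rng=rng))
            if i > 0:
                layers.append(nn.BatchNorm2d(depth))
            layers.append(nn.LeakyReLU(0.2))
            cin = depth
        layers.append(nn.Conv2d(cin, 1, 4, stride=1, padding=1, rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        side = x.shape[1]
        if self.score_map_size(side) < 1:
            raise ValueError(f"input side {side} too small for the stride stack")
        return self.net(x)

    @classmethod
    def score_map_size(cls, size: int) -> int:
        for _, stride in cls._PLAN:
            size = conv_output_size(size, 4, stride, 1)
        return conv_output_size(size, 4, 1, 1)


def build_model(config: NetworkConfig) -> nn.Module:
    """Instantiate the denoiser for ``config.family`` (builders are pure:
    the same config always yields identical layer specs and weights)."""
    if config.family == "dncnn":
        return DnCNN(config)
    if config.family == "udncnn":
        return UDnCNN(config)
    if config.family == "dudncnn":
        return DUDnCNN(config)
    if config.family == "attngan":
        return AttnUNet(config)
    raise ValueError(f"unknown family '{config.family}'")


def build_discriminator(config: NetworkConfig) -> PixelDiscriminator:
    if config.family != "attngan":
        raise ValueError("the discriminator belongs to the attngan family")
    return PixelDiscriminator(config)


def denoise(model: nn.Module, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Run a trained model over (N, H, W) images; output clipped to >= 0."""
    model.eval()
    images = np.asarray(images, dtype=np.float32)
    out = np.empty_like(images)
    for start in range(0, images.shape[0], batch_size):
        chunk = images[start:start + batch_size]
        pred = model(Tensor(chunk[..., None])).numpy()
        out[start:start + chunk.shape[0]] = np.clip(pred[..., 0], 0.0, None)
    return out


def save_checkpoint(model: nn.Module, path) -> None:
    """Checkpoint = weight arrays + the YAML-serialized config."""
    state = model.state_dict()
    state["__config__"] = np.bytes_(model.config.to_yaml().encode())
    np.savez_compressed(path, **state)


def load_checkpoint(path) -> nn.Module:
    with np.load(path) as archive:
        config = NetworkConfig.from_yaml(bytes(archive["__config__"]).decode())
        model = build_model(config)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state_dict(state)
    return model
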