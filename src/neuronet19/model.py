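"""NeuroNet19: VGG19 convolutional backbone + inverted pyramid pooling.

The backbone is the 16-convolution / 5-maxpool VGG19 feature stack
(fully-connected layers discarded — only a spatial map can feed the
pooling levels), so a 128x128 input yields a 4x4x512 feature map.  The
inverted pyramid pooling module (iPPM) processes that map at several
scales: for each pool size ``s`` it nearest-upsamples by ``s``, max-pools
with window and stride ``s`` (restoring the original H x W), applies a
1x1 convolution, and concatenates the per-level outputs channel-wise.

Because the pooling windows align exactly with the blocks of repeated
pixels the upsampling produced, maxpool_s(upsample_s(X)) == X identically;
each level is therefore numerically a 1x1 convolution of its input.  The
module implements the stages literally and the identity is asserted in the
test suite rather than exploited.

After the iPPM come two 3x3 convolutions (256 and 128 filters, ReLU),
global average pooling, and a softmax dense layer over the four classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (Concat, Conv2D, Dense, GlobalAvgPool, MaxPool2D, Network,
                     ReLU, Sequential, UpsampleNearest, max_pool,
                     upsample_nearest)

__all__ = [
    "IPPMConfig",
    "ModelConfig",
    "PretrainedWeightsUnavailable",
    "build_backbone",
    "backbone_output_shape",
    "ippm_level",
    "ippm",
    "build_neuronet19",
    "extract_embeddings",
    "prepare_batch",
]

# VGG19 feature stack: (out_channels, n_convs) per block, pool2 after each
_VGG19_BLOCKS = ((64, 2), (128, 2), (256, 4), (512, 4), (512, 4))
_TINY_BLOCKS = ((16, 1), (32, 1), (64, 1))


class PretrainedWeightsUnavailable(RuntimeError):
    pass


@dataclass(frozen=True)
class IPPMConfig:
    """Pyramid pooling: pool sizes double as upsampling factors; each level
    ends in a ``level_kernel`` x ``level_kernel`` convolution with
    ``level_filters`` outputs.  ``include_identity_branch`` optionally adds
    the raw feature map to the concatenation (off by default: the module
    concatenates the pyramid levels only)."""

    pool_sizes: tuple[int, ...] = (2, 3, 4, 6)
    level_filters: int = 128
    level_kernel: int = 1
    include_identity_branch: bool = False

    def validate(self) -> None:
        if not self.pool_sizes or any(s < 2 for s in self.pool_sizes):
            raise ValueError("pool_sizes must be nonempty with every size >= 2")
        if self.level_filters < 1:
            raise ValueError("level_filters must be >= 1")
        if self.level_kernel < 1 or self.level_kernel % 2 == 0:
            raise ValueError("level_kernel must be odd and >= 1")


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 128
    input_channels: int = 1
    pretrained_backbone: bool = False
    ippm: IPPMConfig = field(default_factory=IPPMConfig)
    head_filters: tuple[int, int] = (256, 128)
    num_classes: int = 4
    backbone_variant: str = "vgg19"  # "vgg19" | "tiny"

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if len(self.head_filters) != 2:
            raise ValueError("head_filters must have length 2")
        if self.backbone_variant not in ("vgg19", "tiny"):
            raise ValueError(f"unknown backbone_variant {self.backbone_variant!r}")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        self.ippm.validate()

    @staticmethod
    def tiny(input_size: int = 64, num_classes: int = 4) -> "ModelConfig":
        """CPU-scale preset: 3-block backbone, narrow iPPM and head.

        Same architecture contracts as the full model (backbone -> iPPM ->
        two 3x3 convs -> GAP -> softmax), sized for desk-scale runs.
        """
        return ModelConfig(
            input_size=input_size,
            backbone_variant="tiny",
            ippm=IPPMConfig(level_filters=32),
            head_filters=(128, 64),
            num_classes=num_classes,
        )


def _blocks(config: ModelConfig):
    return _VGG19_BLOCKS if config.backbone_variant == "vgg19" else _TINY_BLOCKS


def backbone_output_shape(config: ModelConfig) -> tuple[int, int, int]:
    """(H, W, C) of the backbone output: one spatial halving per block."""
    blocks = _blocks(config)
    size = config.input_size // (2 ** len(blocks))
    return (size, size, blocks[-1][0])


def build_backbone(config: ModelConfig, rng: np.random.Generator) -> Sequential:
    """Convolutional feature stack truncated after the last pooling layer."""
    config.validate()
    if config.pretrained_backbone:
        raise PretrainedWeightsUnavailable(
            "ImageNet-pretrained VGG19 convolutional weights "
            "(vgg19 imagenet checkpoint) are not available in this "
            "installation; use pretrained_backbone=False for random "
            "initialization or supply weights via load_state_dict.")
    layers: list = []
    in_ch = config.input_channels
    for out_ch, n_convs in _blocks(config):
        for _ in range(n_convs):
            layers += [Conv2D(in_ch, out_ch, 3, rng), ReLU()]
            in_ch = out_ch
        layers.append(MaxPool2D(2))
    return Sequential(layers)


def ippm_level(fmap: np.ndarray, s: int, filters: int, kernel: int = 1,
               rng: np.random.Generator | None = None,
               conv: Conv2D | None = None) -> np.ndarray:
    """One pyramid level applied functionally to a feature map.

    Nearest-upsample by ``s``, max-pool with window/stride ``s`` (restoring
    H x W), then a ``kernel`` x ``kernel`` convolution with ``filters``
    outputs.  Pass ``conv`` to reuse existing weights, otherwise a fresh
    He-initialized convolution is drawn from ``rng``.
    """
    if s < 2:
        raise ValueError("pool size must be >= 2")
    x = np.asarray(fmap, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    pooled = max_pool(upsample_nearest(x, s), s)
    if conv is None:
        conv = Conv2D(x.shape[-1], filters, kernel,
                      rng if rng is not None else np.random.default_rng(0))
    out = conv.forward(pooled)
    return out[0] if squeeze else out


def _make_ippm(in_channels: int, config: IPPMConfig,
               rng: np.random.Generator) -> Concat:
    branches: list = []
    if config.include_identity_branch:
        branches.append(Sequential([]))
    for s in config.pool_sizes:
        branches.append(Sequential([
            UpsampleNearest(s),
            MaxPool2D(s),
            Conv2D(in_channels, config.level_filters, config.level_kernel, rng),
        ]))
    return Concat(branches)


def ippm(fmap: np.ndarray, config: IPPMConfig = IPPMConfig(),
         rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialized pyramid module to a feature map.

    Output channels: ``len(pool_sizes) * level_filters`` (plus the input
    width when the identity branch is enabled), spatial dims preserved,
    levels concatenated in ``pool_sizes`` order.
    """
    config.validate()
    x = np.asarray(fmap, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    module = _make_ippm(x.shape[-1], config,
                        rng if rng is not None else np.random.default_rng(0))
    out = module.forward(x)
    return out[0] if squeeze else out


def build_neuronet19(config: ModelConfig = ModelConfig(), seed: int = 0) -> Network:
    """Assemble the full classifier; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(int(seed))
    backbone = build_backbone(config, rng)
    _, _, c = backbone_output_shape(config)
    pyramid = _make_ippm(c, config.ippm, rng)
    concat_ch = len(config.ippm.pool_sizes) * config.ippm.level_filters
    if config.ippm.include_identity_branch:
        concat_ch += c
    f0, f1 = config.head_filters
    features = Sequential([
        backbone,
        pyramid,
        Conv2D(concat_ch, f0, 3, rng), ReLU(),
        Conv2D(f0, f1, 3, rng), ReLU(),
        GlobalAvgPool(),
    ])
    head = Dense(f1, config.num_classes, rng)
    net = Network(features, head)
    net.config = config
    return net


def prepare_batch(images: np.ndarray) -> np.ndarray:
    """Gray uint8 (N, H, W) or (H, W) -> zero-centred float32 (N, H, W, 1).

    Pixels are scaled to [-1, 1] (x / 127.5 - 1).  Centring matters: with
    all-positive inputs every first-layer weight gradient shares the sign
    of its unit's error term, which slows early convergence badly.
    """
    x = np.asarray(images)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    return x.astype(np.float32) / 127.5 - 1.0


def extract_embeddings(model: Network, images: np.ndarray) -> np.ndarray:
    """Penultimate (global-average-pooled) vectors, one row per image."""
    return model.embeddings(prepare_batch(images))
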