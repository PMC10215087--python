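"""Reusable network pieces: two-conv stage nodes, pre-/post-processors and
the three resampling operators D (max-pool down), U (up-sample to full
resolution) and V (up-sample to an intermediate stage scale).

A stage node is the ``3x3,k 3x3,k`` subnetwork that realises one RK
stage/slope/increment function; its output width is always ``k``
regardless of how many tensors are concatenated at its input, and same
padding keeps the spatial size unchanged.  Down-sampling is max pooling
and up-sampling is parameter-free interpolation, so every trainable scalar
of the network lives in the nodes and the final 1x1 classifier.
"""

from __future__ import annotations

import numpy as np

from . import nn as F
from .config import ArchitectureConfig
from .nn import Conv2d, Identity, InstanceNorm2d, Module, Tensor


class ConvNormAct(Module):
    """One 3x3 convolution followed by normalization and leaky ReLU."""

    def __init__(self, in_channels, out_channels, rng, norm_kind="instance",
                 dtype=np.float32, slope=0.01):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng, dtype=dtype)
        self.norm = (InstanceNorm2d(out_channels, dtype=dtype)
                     if norm_kind == "instance" else Identity())
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(self.norm(self.conv(x)), self.slope)


class StageSubnetwork(Module):
    """Two-conv node (a -> k then k -> k); houses the E/X/I/R stage functions."""

    def __init__(self, in_channels: int, out_channels: int, rng,
                 norm_kind: str = "instance", dtype=np.float32):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("node channel counts must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.block1 = ConvNormAct(in_channels, out_channels, rng, norm_kind, dtype)
        self.block2 = ConvNormAct(out_channels, out_channels, rng, norm_kind, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))

    def zero_final_conv(self):
        """Zero the second conv (weights and bias): the node then emits zeros."""
        self.block2.conv.weight.data[...] = 0.0
        self.block2.conv.bias.data[...] = 0.0


class PreProcessor(StageSubnetwork):
    """Full-resolution node mapping the image (in_channels) to the state width k."""


class PostProcessor(Module):
    """``3x3,k 3x3,k 1x1,c``: decodes the final state y1 into class logits."""

    def __init__(self, width: int, num_classes: int, rng,
                 norm_kind: str = "instance", dtype=np.float32):
        super().__init__()
        if width < 1 or num_classes < 1:
            raise ValueError("post-processor dimensions must be positive")
        self.width = width
        self.num_classes = num_classes
        self.block1 = ConvNormAct(width, width, rng, norm_kind, dtype)
        self.block2 = ConvNormAct(width, width, rng, norm_kind, dtype)
        self.classifier = Conv2d(width, num_classes, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.block2(self.block1(x)))


def make_node(in_channels, width, cfg: ArchitectureConfig | None = None,
              rng=None, dtype=np.float32) -> StageSubnetwork:
    rng = rng if rng is not None else np.random.default_rng(0)
    norm = cfg.norm_kind if cfg is not None else "instance"
    return StageSubnetwork(in_channels, width, rng, norm, dtype)


def make_pre(in_channels, width, cfg: ArchitectureConfig | None = None,
             rng=None, dtype=np.float32) -> PreProcessor:
    rng = rng if rng is not None else np.random.default_rng(0)
    norm = cfg.norm_kind if cfg is not None else "instance"
    return PreProcessor(in_channels, width, rng, norm, dtype)


def make_post(width, num_classes, cfg: ArchitectureConfig | None = None,
              rng=None, dtype=np.float32) -> PostProcessor:
    rng = rng if rng is not None else np.random.default_rng(0)
    norm = cfg.norm_kind if cfg is not None else "instance"
    return PostProcessor(width, num_classes, rng, norm, dtype)


# ------------------------------------------------------------- D, U, V ----

def downsample_D(feature: Tensor, from_divisor: int, to_divisor: int,
                 pad_policy: str = "pad_and_crop") -> Tensor:
    """Down-sample from scale 1/from_divisor to 1/to_divisor by repeated
    2x2 max pooling.  ``to_divisor == from_divisor`` is the identity."""
    if to_divisor < from_divisor:
        raise ValueError(f"D cannot up-sample ({from_divisor} -> {to_divisor})")
    steps = _log2_ratio(to_divisor, from_divisor, "D")
    out = feature
    for _ in range(steps):
        h, w = out.data.shape[2], out.data.shape[3]
        if (h % 2 or w % 2) and pad_policy == "reject":
            raise ValueError(f"spatial size {(h, w)} not divisible by 2")
        out = F.max_pool2(out)
    return out


def upsample_U(feature: Tensor, from_divisor: int,
               mode: str = "bilinear") -> Tensor:
    """Up-sample an increment from its stage scale back to full resolution."""
    return upsample_V(feature, from_divisor, 1, mode=mode)


def upsample_V(feature: Tensor, from_divisor: int, to_divisor: int,
               mode: str = "bilinear") -> Tensor:
    """Up-sample from scale 1/from_divisor to the (finer) 1/to_divisor."""
    if to_divisor > from_divisor:
        raise ValueError(f"V cannot down-sample ({from_divisor} -> {to_divisor})")
    factor = 2 ** _log2_ratio(from_divisor, to_divisor, "V")
    return F.upsample(feature, factor, mode=mode)


def resample(feature: Tensor, from_divisor: int, to_divisor: int,
             mode: str = "bilinear", pad_policy: str = "pad_and_crop") -> Tensor:
    """Route to D or V depending on the direction of the scale change."""
    if to_divisor >= from_divisor:
        return downsample_D(feature, from_divisor, to_divisor, pad_policy)
    return upsample_V(feature, from_divisor, to_divisor, mode=mode)


def _log2_ratio(big: int, small: int, op: str) -> int:
    if big % small:
        raise ValueError(f"{op}: scale divisors must be power-of-two multiples")
    ratio = big // small
    steps = int(ratio).bit_length() - 1
    if 2**steps != ratio:
        raise ValueError(f"{op}: scale ratio {ratio} is not a power of two")
    return steps
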