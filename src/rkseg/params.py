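"""Closed-form trainable-parameter counts for RKSeg variants.

Every stage node is a pair of 3x3 convolutions (a -> k then k -> k), each
carrying a bias and followed by a per-channel normalization with a
learnable affine pair, so a node costs

    node(a -> k) = 9*a*k + 9*k^2 + 2*k (conv biases) + 4*k (norm affine).

The pre-processor is one such node at full resolution (in_channels -> k);
the post-processor is a node (k -> k) plus a 1x1 conv (k*c weights + c
biases).  Backbone E has ``s`` stage nodes whose input widths are
k, 2k, ..., s*k (the state plus the accumulated increments); backbones
I and R add ``s`` increment nodes, each consuming the full ``s*k`` input
(the state plus s-1 slope/increment tensors).  The orientation (which end
of the scale pyramid a node sits at) never changes the count.

Counting convention: trainable scalars only -- conv weights, conv biases
and normalization affine pairs; running statistics are not parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ArchitectureConfig, validate_config


def node_param_count(a: int, k: int, norm: bool = True) -> int:
    """Trainable scalars of a two-conv stage node with input width ``a``."""
    count = 9 * a * k + k * 9 * k + 2 * k
    if norm:
        count += 4 * k
    return count


@dataclass(frozen=True)
class ParameterCountReport:
    """Total and per-component trainable-scalar counts of one variant."""

    total: int
    per_component: dict[str, int]

    @property
    def total_millions_2dp(self) -> float:
        """Millions of parameters, half-up to two decimals (table format)."""
        return round_half_up_millions(self.total)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "per_component": dict(self.per_component),
            "total_millions_2dp": self.total_millions_2dp,
        }


def round_half_up_millions(total: int) -> float:
    # int arithmetic: avoids banker's rounding on exact .xx5 boundaries
    return ((total * 100 + 500_000) // 1_000_000) / 100.0


def count_parameters_closed_form(cfg: ArchitectureConfig) -> ParameterCountReport:
    """Analytic trainable-parameter count of the configured variant."""
    validate_config(cfg)
    k, c, s = cfg.width, cfg.num_classes, cfg.stages
    norm = cfg.norm_kind != "none"
    per: dict[str, int] = {}
    per["pre_processor"] = node_param_count(cfg.in_channels, k, norm)
    if cfg.backbone == "E":
        for i in range(1, s + 1):
            per[f"stage_E{i}"] = node_param_count(k * i, k, norm)
    else:
        for i in range(1, s + 1):
            per[f"stage_X{i}"] = node_param_count(k * i, k, norm)
        for i in range(1, s + 1):
            per[f"stage_{cfg.backbone}{i}"] = node_param_count(k * s, k, norm)
    per["post_processor"] = node_param_count(k, k, norm) + (k * c + c)
    return ParameterCountReport(total=sum(per.values()), per_component=per)
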