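"""Architecture and training configuration.

An RKSeg network computes a single time step of an s-stage Runge-Kutta
integrator: a pre-processor maps the image to the initial state ``y0``,
each RK stage produces an increment ``e_i`` at its own spatial scale, and
the final state ``y1 = y0 + sum_i U(e_i)`` is decoded into class logits by
a post-processor.  The configuration below pins down one member of the
family:

* ``orientation`` -- ``"L"`` runs the stages from large scale to small
  scale, ``"R"`` reverses that order.
* ``backbone`` -- the stage-wiring scheme: ``"E"`` (explicit: each
  increment sees the state and all previous increments), ``"I"`` (implicit:
  slope nodes X_i first, then increment nodes I_i that also see the later
  slopes), ``"R"`` (reduced implicit: increment nodes see only the slopes).
* ``depth`` -- number of distinct halved scales, which equals the total
  number of stage nodes.  For backbone E the stage count ``s`` equals the
  depth; for I and R each stage spends two nodes (an X and an I/R node), so
  the depth must be even and ``s = depth / 2``.
* ``width`` -- the constant per-node output channel count ``k`` (unlike
  U-Net-style models the width does not grow with depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator

import yaml

ORIENTATIONS = ("L", "R")
BACKBONES = ("E", "I", "R")
INTERPOLATION_MODES = ("bilinear", "nearest")
NORM_KINDS = ("instance", "none")
PAD_POLICIES = ("pad_and_crop", "reject")


class ConfigError(ValueError):
    """Raised when an architecture or training configuration is invalid."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters that determine one RKSeg variant.

    Parameters
    ----------
    orientation : {"L", "R"}
        Large-to-small ("L") or small-to-large ("R") stage scale order.
    backbone : {"E", "I", "R"}
        Stage wiring scheme (explicit / implicit / reduced implicit).
    depth : int
        Number of halved scales; equals the number of stage nodes.
    width : int
        Output channels ``k`` of every node, constant across scales.
    in_channels : int
        Image modalities (e.g. 4 for multimodal MRI).
    num_classes : int
        Segmentation classes including background.
    """

    orientation: str = "L"
    backbone: str = "E"
    depth: int = 3
    width: int = 32
    in_channels: int = 1
    num_classes: int = 2
    interpolation_mode: str = "bilinear"
    norm_kind: str = "instance"
    pad_policy: str = "pad_and_crop"

    @property
    def stages(self) -> int:
        """Number of RK stages ``s`` (``depth`` for E, ``depth // 2`` for I/R)."""
        return self.depth if self.backbone == "E" else self.depth // 2

    def validate(self) -> "ArchitectureConfig":
        return validate_config(self)

    def to_dict(self) -> dict[str, Any]:
        return {
            "orientation": self.orientation,
            "backbone": self.backbone,
            "depth": self.depth,
            "width": self.width,
            "in_channels": self.in_channels,
            "num_classes": self.num_classes,
            "interpolation_mode": self.interpolation_mode,
            "norm_kind": self.norm_kind,
            "pad_policy": self.pad_policy,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ArchitectureConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown architecture fields: {sorted(extra)}")
        return cls(**d).validate()


def validate_config(cfg: ArchitectureConfig) -> ArchitectureConfig:
    """Check every structural invariant; return ``cfg`` unchanged if valid.

    Raises
    ------
    ConfigError
        On any violation: odd depth with an alternating (I/R) backbone,
        fewer than two stages for I/R, non-positive dimensions, or unknown
        enum values.
    """
    if cfg.orientation not in ORIENTATIONS:
        raise ConfigError(f"orientation must be one of {ORIENTATIONS}, got {cfg.orientation!r}")
    if cfg.backbone not in BACKBONES:
        raise ConfigError(f"backbone must be one of {BACKBONES}, got {cfg.backbone!r}")
    if cfg.interpolation_mode not in INTERPOLATION_MODES:
        raise ConfigError(f"interpolation_mode must be one of {INTERPOLATION_MODES}")
    if cfg.norm_kind not in NORM_KINDS:
        raise ConfigError(f"norm_kind must be one of {NORM_KINDS}")
    if cfg.pad_policy not in PAD_POLICIES:
        raise ConfigError(f"pad_policy must be one of {PAD_POLICIES}")
    for name in ("depth", "width", "in_channels", "num_classes"):
        v = getattr(cfg, name)
        if not isinstance(v, int) or v < 1:
            raise ConfigError(f"{name} must be a positive integer, got {v!r}")
    if cfg.backbone in ("I", "R"):
        if cfg.depth % 2 != 0:
            raise ConfigError(
                f"odd depth with alternating backbone: backbone {cfg.backbone!r} "
                f"spends two nodes per stage, so depth must be even (got {cfg.depth})"
            )
        if cfg.depth // 2 < 2:
            raise ConfigError(
                f"backbone {cfg.backbone!r} updates stages alternately and needs "
                f"at least two stages (s = depth/2 = {cfg.depth // 2})"
            )
    return cfg


def node_names(cfg: ArchitectureConfig) -> list[str]:
    """Stage-node names in construction order (X nodes before I/R nodes)."""
    if cfg.backbone == "E":
        return [f"E{i}" for i in range(1, cfg.stages + 1)]
    return [f"X{i}" for i in range(1, cfg.stages + 1)] + [
        f"{cfg.backbone}{i}" for i in range(1, cfg.stages + 1)
    ]


def scale_schedule(cfg: ArchitectureConfig) -> list[tuple[str, int]]:
    """Ordered ``(node_name, scale_divisor)`` pairs for the stage nodes.

    Orientation L places node ``j`` (j = 1..depth, X nodes enumerated before
    I/R nodes) at divisor ``2**j`` -- the first stage works at half
    resolution, the last at the coarsest scale.  Orientation R assigns the
    same divisors in reversed order.  The pre- and post-processor always sit
    at full resolution (divisor 1).
    """
    validate_config(cfg)
    names = node_names(cfg)
    divisors = [2**j for j in range(1, cfg.depth + 1)]
    if cfg.orientation == "R":
        divisors = divisors[::-1]
    return list(zip(names, divisors))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: SGD with Nesterov momentum, poly LR decay."""

    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    lr0: float = 0.01
    momentum: float = 0.99
    epochs: int = 150
    batch_size: int = 8
    lr_schedule: str = "poly"  # "poly" (1 - epoch/max)^0.9 or "constant"
    poly_power: float = 0.9
    seed: int = 0
    device: str = "cpu"
    residual_init: bool = False  # zero the last conv of every stage node

    def validate(self) -> "TrainConfig":
        self.arch.validate()
        if self.lr0 <= 0:
            raise ConfigError(f"lr0 must be > 0, got {self.lr0}")
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.lr_schedule not in ("poly", "constant"):
            raise ConfigError("lr_schedule must be 'poly' or 'constant'")
        return self

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "constant":
            return self.lr0
        return self.lr0 * (1.0 - epoch / self.epochs) ** self.poly_power

    def to_dict(self) -> dict[str, Any]:
        d = {
            "lr0": self.lr0,
            "momentum": self.momentum,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "lr_schedule": self.lr_schedule,
            "poly_power": self.poly_power,
            "seed": self.seed,
            "device": self.device,
            "residual_init": self.residual_init,
        }
        d["arch"] = self.arch.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrainConfig":
        d = dict(d)
        arch = d.pop("arch", {})
        if isinstance(arch, dict):
            arch = ArchitectureConfig.from_dict(arch)
        known = {f for f in cls.__dataclass_fields__ if f != "arch"}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown training fields: {sorted(extra)}")
        return cls(arch=arch, **d).validate()


def load_experiment(path) -> dict[str, Any]:
    """Load an experiment config file with ``model``/``data``/``train`` sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a mapping")
    out: dict[str, Any] = {}
    out["model"] = ArchitectureConfig.from_dict(doc.get("model", {}))
    train_section = dict(doc.get("train", {}))
    train_section["arch"] = out["model"].to_dict()
    out["train"] = TrainConfig.from_dict(train_section)
    out["data"] = dict(doc.get("data", {}))
    return out


def with_overrides(cfg: ArchitectureConfig, **kw) -> ArchitectureConfig:
    return replace(cfg, **kw).validate()
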