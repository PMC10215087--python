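"""Assembly and forward pass of the six RKSeg variants.

One forward pass is one time step of an s-stage Runge-Kutta method:

    y1 = y0 + sum_{i=1..s} U(e_i)

where ``y0`` is the pre-processor output (the initial state, k channels at
full resolution), each increment ``e_i`` is computed by a stage node at its
own spatial scale, and ``U`` interpolates increments back to full
resolution before the sum.  The wiring of the stage nodes depends on the
backbone:

* E (explicit): ``e_i = E_i(y0, e_1, .., e_{i-1})`` -- input width k*i.
* I (implicit): slopes first, ``x_i = X_i(y0, x_1, .., x_{i-1})`` (width
  k*i), then ``e_i = I_i(y0, e_1, .., e_{i-1}, x_{i+1}, .., x_s)`` --
  always s tensors, width k*s.
* R (reduced):  ``e_i = R_i(y0, x_1, .., x_{i-1}, x_{i+1}, .., x_s)`` --
  width k*s.

Every tensor entering a node is resampled to that node's scale: max-pool
D when coming from a finer scale (always the case for y0), interpolation
V when coming from a coarser one (orientation R).  Only one time step is
run; accumulating several would compound truncation error without a
matching gain in accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import (
    PostProcessor,
    PreProcessor,
    StageSubnetwork,
    downsample_D,
    resample,
    upsample_U,
)
from .config import ArchitectureConfig, node_names, scale_schedule, validate_config
from .nn import Module, ModuleList, Tensor
from .params import ParameterCountReport


@dataclass
class FeatureState:
    """Named intermediate tensors of one forward pass (numpy views)."""

    y0: np.ndarray
    e: list[np.ndarray] = field(default_factory=list)
    x: list[np.ndarray] = field(default_factory=list)
    y1: np.ndarray | None = None


class RKSegNet(Module):
    """A built RKSeg network: pre-processor, d stage nodes, post-processor."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        validate_config(cfg)
        self.cfg = cfg
        self.dtype = dtype
        rng = rng if rng is not None else np.random.default_rng(0)
        k, s = cfg.width, cfg.stages
        norm = cfg.norm_kind
        self.pre = PreProcessor(cfg.in_channels, k, rng, norm, dtype)
        widths = self.node_input_widths(cfg)
        self.nodes = ModuleList(
            StageSubnetwork(a, k, rng, norm, dtype) for a in widths
        )
        self.post = PostProcessor(k, cfg.num_classes, rng, norm, dtype)
        self.schedule = scale_schedule(cfg)
        self._divisors = [div for _, div in self.schedule]

    # ------------------------------------------------------------ build ----

    @staticmethod
    def node_input_widths(cfg: ArchitectureConfig) -> list[int]:
        """Input channel width of each stage node, in construction order."""
        k, s = cfg.width, cfg.stages
        if cfg.backbone == "E":
            return [k * i for i in range(1, s + 1)]
        return [k * i for i in range(1, s + 1)] + [k * s] * s

    def zero_stage_outputs(self):
        """Zero the final conv of every stage node (identity time step)."""
        for node in self.nodes:
            node.zero_final_conv()

    # ---------------------------------------------------------- forward ----

    def forward(self, image: Tensor | np.ndarray,
                return_state: bool = False):
        """Run one RK time step; return full-resolution class logits.

        ``image`` is (N, in_channels, H, W).  H and W are padded to the next
        multiple of 2**depth when ``pad_policy == 'pad_and_crop'`` and the
        logits cropped back; otherwise non-divisible sizes are rejected.
        """
        cfg = self.cfg
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=self.dtype))
        if image.data.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {image.data.shape}")
        if image.data.shape[1] != cfg.in_channels:
            raise ValueError(
                f"channel mismatch: model expects {cfg.in_channels}, "
                f"got {image.data.shape[1]}"
            )
        h, w = image.data.shape[2], image.data.shape[3]
        div_full = 2**cfg.depth
        pad_h = (-h) % div_full
        pad_w = (-w) % div_full
        if pad_h or pad_w:
            if cfg.pad_policy == "reject":
                raise ValueError(
                    f"spatial size {(h, w)} not divisible by 2**depth = {div_full}"
                )
            image = _pad_symmetric(image, pad_h, pad_w)

        mode = cfg.interpolation_mode
        y0 = self.pre(image)
        state = FeatureState(y0=y0.data)
        s = cfg.stages
        divisors = self._divisors

        if cfg.backbone == "E":
            e: list[Tensor] = []
            e_div: list[int] = []
            for i in range(s):
                div = divisors[i]
                inputs = [downsample_D(y0, 1, div, cfg.pad_policy)]
                inputs += [resample(e[j], e_div[j], div, mode, cfg.pad_policy)
                           for j in range(i)]
                ei = self.nodes[i](nn.concat(inputs))
                e.append(ei)
                e_div.append(div)
        else:
            x_div = divisors[:s]
            e_div = divisors[s:]
            x: list[Tensor] = []
            for i in range(s):
                div = x_div[i]
                inputs = [downsample_D(y0, 1, div, cfg.pad_policy)]
                inputs += [resample(x[j], x_div[j], div, mode, cfg.pad_policy)
                           for j in range(i)]
                x.append(self.nodes[i](nn.concat(inputs)))
            state.x = [t.data for t in x]
            e = []
            for i in range(s):
                div = e_div[i]
                inputs = [downsample_D(y0, 1, div, cfg.pad_policy)]
                if cfg.backbone == "I":
                    inputs += [resample(e[j], e_div[j], div, mode, cfg.pad_policy)
                               for j in range(i)]
                    inputs += [resample(x[j], x_div[j], div, mode, cfg.pad_policy)
                               for j in range(i + 1, s)]
                else:  # R
                    inputs += [resample(x[j], x_div[j], div, mode, cfg.pad_policy)
                               for j in range(s) if j != i]
                e.append(self.nodes[s + i](nn.concat(inputs)))

        state.e = [t.data for t in e]
        increments = [upsample_U(t, div, mode) for t, div in zip(e, e_div)]
        y1 = nn.add_n([y0] + increments)
        state.y1 = y1.data
        logits = self.post(y1)
        if pad_h or pad_w:
            logits = _crop(logits, pad_h, pad_w)
        if return_state:
            return logits, state
        return logits

    # ----------------------------------------------------------- counts ----

    def count_parameters_instantiated(self) -> ParameterCountReport:
        """Brute-force per-scalar count over the built modules."""
        names = node_names(self.cfg)
        per: dict[str, int] = {
            "pre_processor": self.pre.num_parameters(),
        }
        for name, node in zip(names, self.nodes):
            per[f"stage_{name}"] = node.num_parameters()
        per["post_processor"] = self.post.num_parameters()
        return ParameterCountReport(total=sum(per.values()), per_component=per)

    def describe(self) -> str:
        """Human-readable node/width/scale table (``rkseg build --dry-run``)."""
        rows = [f"RKSeg-{self.cfg.orientation} backbone {self.cfg.backbone} "
                f"d={self.cfg.depth} s={self.cfg.stages} k={self.cfg.width} "
                f"in={self.cfg.in_channels} c={self.cfg.num_classes}"]
        rows.append(f"{'node':<14}{'in_width':>9}{'out_width':>10}{'scale':>9}")
        rows.append(f"{'pre':<14}{self.cfg.in_channels:>9}{self.cfg.width:>10}{'1/1':>9}")
        widths = self.node_input_widths(self.cfg)
        for (name, div), a in zip(self.schedule, widths):
            rows.append(f"{name:<14}{a:>9}{self.cfg.width:>10}{f'1/{div}':>9}")
        rows.append(f"{'post':<14}{self.cfg.width:>9}{self.cfg.num_classes:>10}{'1/1':>9}")
        rows.append(f"trainable parameters: {self.num_parameters():,}")
        return "\n".join(rows)

    # ------------------------------------------------------- checkpoints ----

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, sd: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(sd)
        extra = set(sd) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(sd[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)

    def save(self, path):
        arrays = {f"param:{k}": v for k, v in self.state_dict().items()}
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "RKSegNet":
        with np.load(path) as npz:
            cfg_json = bytes(npz["config_json"]).decode()
            cfg = ArchitectureConfig.from_dict(json.loads(cfg_json))
            net = cls(cfg)
            sd = {k[len("param:"):]: npz[k] for k in npz.files if k.startswith("param:")}
        net.load_state_dict(sd)
        return net


def build_rkseg(cfg: ArchitectureConfig, seed: int = 0,
                dtype=np.float32) -> RKSegNet:
    """Build one of the six variants with a seeded weight initialization."""
    return RKSegNet(cfg, rng=np.random.default_rng(seed), dtype=dtype)


def _pad_symmetric(image: Tensor, pad_h: int, pad_w: int) -> Tensor:
    top, left = pad_h // 2, pad_w // 2
    bottom, right = pad_h - top, pad_w - left
    data = np.pad(image.data, ((0, 0), (0, 0), (top, bottom), (left, right)))
    out = Tensor(data, parents=(image,))

    def backward(g):
        h, w = image.data.shape[2], image.data.shape[3]
        image._accumulate(g[:, :, top:top + h, left:left + w])

    out._backward = backward if (image.requires_grad or image._parents) else None
    return out


def _crop(logits: Tensor, pad_h: int, pad_w: int) -> Tensor:
    top, left = pad_h // 2, pad_w // 2
    h = logits.data.shape[2] - pad_h
    w = logits.data.shape[3] - pad_w
    data = logits.data[:, :, top:top + h, left:left + w]
    out = Tensor(data, parents=(logits,))

    def backward(g):
        full = np.zeros_like(logits.data)
        full[:, :, top:top + h, left:left + w] = g
        logits._accumulate(full)

    out._backward = backward
    return out
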