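"""Training, evaluation and prediction around the RKSeg networks.

The public surface follows the model/results idiom: construct an
:class:`RKSeg` model object from an architecture plus optimization
settings, call :meth:`RKSeg.fit` on (train, validation) samples, and
receive an :class:`RKSegResults` carrying the fitted weights, per-epoch
loss and validation Dice history, and a ``summary()`` table.  Prediction
and evaluation hang off the results object; ``save``/``load`` round-trip
the fitted network bitwise.

Optimization is plain minibatch SGD with Nesterov momentum (default
initial learning rate 0.01, momentum 0.99 -- the configuration the
architecture family was designed to train under) and a polynomial
learning-rate decay ``lr0 * (1 - epoch/epochs)**0.9``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import ArchitectureConfig, TrainConfig
from .losses import DiceReport, dice_ce_loss, evaluate_dataset
from .model import RKSegNet, build_rkseg
from .nn import SGD, no_grad
from .synth import SegmentationSample


@dataclass
class TrainState:
    """Mutable bookkeeping of one fit: epoch counter and append-only logs."""

    epoch: int = 0
    train_loss: list[float] = field(default_factory=list)
    val_reports: list[DiceReport] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mean: float = -np.inf


class RKSeg:
    """A segmentation model: one RKSeg variant plus its training recipe.

    Parameters
    ----------
    arch : ArchitectureConfig or TrainConfig
        Passing a TrainConfig fixes the full recipe; passing an
        ArchitectureConfig uses default optimization settings, overridable
        through keyword arguments (``lr0``, ``momentum``, ``epochs``,
        ``batch_size``, ``seed``, ...).
    """

    def __init__(self, arch, **train_overrides):
        if isinstance(arch, TrainConfig):
            if train_overrides:
                arch = TrainConfig.from_dict(
                    {**arch.to_dict(), **train_overrides}
                )
            self.train_cfg = arch.validate()
        elif isinstance(arch, ArchitectureConfig):
            self.train_cfg = TrainConfig.from_dict(
                {"arch": arch.to_dict(), **train_overrides}
            )
        else:
            raise TypeError("arch must be ArchitectureConfig or TrainConfig")
        self.arch = self.train_cfg.arch

    @classmethod
    def from_config(cls, path) -> "RKSeg":
        from .config import load_experiment

        return cls(load_experiment(path)["train"])

    def build(self) -> RKSegNet:
        net = build_rkseg(self.arch, seed=self.train_cfg.seed)
        if self.train_cfg.residual_init:
            net.zero_stage_outputs()
        return net

    def fit(self, train_set: Sequence[SegmentationSample],
            val_set: Sequence[SegmentationSample] | None = None,
            log: Callable[[str], None] | None = None) -> "RKSegResults":
        """Run the configured number of epochs of minibatch SGD."""
        tc = self.train_cfg
        train_set = list(train_set)
        if not train_set:
            raise ValueError("empty training set")
        c = self.arch.num_classes
        for s in train_set:
            if s.image.shape[0] != self.arch.in_channels:
                raise ValueError(
                    f"sample {s.case_id} has {s.image.shape[0]} channels, "
                    f"model expects {self.arch.in_channels}"
                )
            if int(s.label.max()) >= c:
                raise ValueError(
                    f"sample {s.case_id} contains label {int(s.label.max())} "
                    f">= num_classes {c}"
                )
        rng = np.random.default_rng(tc.seed)
        net = self.build()
        opt = SGD(net.parameters(), lr=tc.lr0, momentum=tc.momentum,
                  nesterov=True)
        state = TrainState()
        n = len(train_set)
        t0 = time.time()
        for epoch in range(tc.epochs):
            opt.lr = tc.lr_at(epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                batch = np.stack([train_set[i].image for i in idx])
                labels = np.stack([train_set[i].label for i in idx])
                logits = net.forward(batch)
                loss = dice_ce_loss(logits, labels)
                val = float(loss.data)
                if not np.isfinite(val):
                    raise RuntimeError(
                        f"non-finite loss {val} at epoch {epoch}, "
                        f"batch starting {start} (lr={opt.lr:.4g})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(val)
            state.epoch = epoch + 1
            state.train_loss.append(float(np.mean(losses)))
            state.lr.append(opt.lr)
            line = (f"epoch {epoch + 1:3d}/{tc.epochs}  "
                    f"loss {state.train_loss[-1]:.4f}  lr {opt.lr:.4g}")
            if val_set:
                report = evaluate_dataset(net, val_set,
                                          batch_size=tc.batch_size)
                state.val_reports.append(report)
                if report.mean > state.best_val_mean:
                    state.best_val_mean = report.mean
                    state.best_epoch = epoch + 1
                    best_weights = net.state_dict()
                line += f"  val mean DSC {report.mean:.4f}"
            if log:
                log(line)
        best = best_weights if val_set else net.state_dict()
        return RKSegResults(
            model=net, train_cfg=tc, state=state,
            best_weights=best, n_train=n,
            n_val=len(val_set) if val_set else 0,
            wall_time=time.time() - t0,
        )


class RKSegResults:
    """Fitted model, training history and evaluation/prediction helpers."""

    def __init__(self, model: RKSegNet, train_cfg: TrainConfig,
                 state: TrainState, best_weights, n_train: int, n_val: int,
                 wall_time: float):
        self.model = model
        self.train_cfg = train_cfg
        self.state = state
        self.best_weights = best_weights
        self.n_train = n_train
        self.n_val = n_val
        self.wall_time = wall_time

    # ------------------------------------------------------------ views ----

    @property
    def loss_history(self) -> list[float]:
        return self.state.train_loss

    @property
    def val_history(self) -> list[DiceReport]:
        return self.state.val_reports

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for i, loss in enumerate(self.state.train_loss):
            row = {"epoch": i + 1, "train_loss": loss, "lr": self.state.lr[i]}
            if i < len(self.state.val_reports):
                rep = self.state.val_reports[i]
                row["val_mean_dsc"] = rep.mean
                for cls, v in rep.per_class.items():
                    row[f"val_dsc_class_{cls}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def use_best_weights(self):
        self.model.load_state_dict(self.best_weights)
        return self

    def summary(self) -> str:
        cfg = self.train_cfg
        a = cfg.arch
        count = self.model.count_parameters_instantiated()
        lines = [
            "RKSeg fit results",
            "=" * 56,
            f"variant        RKSeg-{a.orientation} / backbone {a.backbone}",
            f"depth / stages {a.depth} / {a.stages}    width k = {a.width}",
            f"channels in    {a.in_channels}    classes {a.num_classes}",
            f"parameters     {count.total:,} ({count.total_millions_2dp:.2f} M)",
            f"optimizer      SGD(nesterov), lr0={cfg.lr0}, "
            f"momentum={cfg.momentum}, schedule={cfg.lr_schedule}",
            f"epochs         {self.state.epoch}    batch {cfg.batch_size}"
            f"    seed {cfg.seed}",
            f"train cases    {self.n_train}    val cases {self.n_val}",
            f"final loss     {self.state.train_loss[-1]:.4f}",
        ]
        if self.state.val_reports:
            rep = self.state.val_reports[-1]
            lines.append(f"final val DSC  {rep.mean:.4f} "
                         f"(per class {({k: round(v, 4) for k, v in rep.per_class.items()})})")
            lines.append(f"best val DSC   {self.state.best_val_mean:.4f} "
                         f"at epoch {self.state.best_epoch}")
        lines.append(f"wall time      {self.wall_time:.1f} s")
        lines.append("=" * 56)
        return "\n".join(lines)

    # ---------------------------------------------------------- actions ----

    def predict(self, images) -> np.ndarray:
        return predict(self.model, images)

    def evaluate(self, samples, batch_size: int | None = None) -> DiceReport:
        return evaluate_dataset(
            self.model, samples,
            batch_size=batch_size or self.train_cfg.batch_size,
        )

    def save(self, path):
        self.model.save(path)


def predict(model: RKSegNet, images) -> np.ndarray:
    """Argmax label maps for one (C, H, W) image or an (N, C, H, W) batch.

    Odd-sized inputs are padded internally and the prediction cropped back,
    so the output always matches the input's spatial size.
    """
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    with no_grad():
        logits = model.forward(arr)
    labels = np.argmax(logits.data, axis=1).astype(np.uint8)
    return labels[0] if single else labels


def evaluate(model_or_path, samples, batch_size: int = 8) -> DiceReport:
    """Evaluate a built model or a saved checkpoint on a dataset."""
    model = model_or_path
    if isinstance(model_or_path, (str, Path)):
        model = RKSegNet.load(model_or_path)
    return evaluate_dataset(model, samples, batch_size=batch_size)
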