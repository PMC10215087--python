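"""Training loss (cross-entropy + soft Dice) and the Dice evaluation metric.

The evaluation metric is the Dice similarity coefficient
``DSC = 2|A ∩ B| / (|A| + |B|)`` computed per foreground class.  The
training loss follows the common medical-segmentation recipe: pixel-wise
cross-entropy plus a soft-Dice term on softmax probabilities, equally
weighted.  The soft Dice is batch-aggregated per class (one Dice fraction
per class over all pixels of the minibatch), smoothed with ``eps`` in both
numerator and denominator, and averaged over foreground classes only.
The loss is reported in the ``CE + (1 - Dice)`` sign convention, so a
perfect prediction drives it towards 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Tensor
from .nn.autodiff import _make


@dataclass
class DiceReport:
    """Per-class and mean DSC over a set of cases (foreground classes only)."""

    per_class: dict[int, float]
    mean: float
    n_cases: int

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "mean": self.mean,
            "n_cases": self.n_cases,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def dice_coefficient(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """DSC between two binary masks; both-empty pairs score 1 by convention."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    ref_mask = np.asarray(ref_mask).astype(bool)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError(
            f"shape mismatch: {pred_mask.shape} vs {ref_mask.shape}"
        )
    denom = int(pred_mask.sum()) + int(ref_mask.sum())
    if denom == 0:
        return 1.0
    inter = int(np.logical_and(pred_mask, ref_mask).sum())
    return 2.0 * inter / denom


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def dice_ce_loss(logits: Tensor, labels: np.ndarray, eps: float = 1e-5,
                 include_background: bool = False) -> Tensor:
    """Cross-entropy + soft-Dice loss with an analytic gradient.

    Parameters
    ----------
    logits : Tensor, shape (N, C, H, W)
    labels : integer array, shape (N, H, W), values in ``0..C-1``.
    eps : float
        Smoothing added to the soft-Dice numerator and denominator.
    include_background : bool
        Whether class 0 enters the Dice average (off by default, matching
        common segmentation practice; with a single class it is forced on).
    """
    z = logits.data
    if z.ndim != 4:
        raise ValueError(f"logits must be (N, C, H, W), got {z.shape}")
    n, c, h, w = z.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(
            f"label values outside [0, {c - 1}]: "
            f"range [{labels.min()}, {labels.max()}]"
        )

    p = _softmax(z)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    npix = n * h * w

    p_true = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    ce = float(-np.log(np.maximum(p_true, 1e-12)).mean())

    fg = list(range(c)) if (include_background or c == 1) else list(range(1, c))
    inter = (p * onehot).sum(axis=(0, 2, 3))
    psum = p.sum(axis=(0, 2, 3))
    tsum = onehot.sum(axis=(0, 2, 3))
    dice_c = (2.0 * inter + eps) / (psum + tsum + eps)
    dice_term = float(1.0 - dice_c[fg].mean())
    loss = ce + dice_term

    def factory():
        def backward(gout):
            # CE gradient
            dz = (p - onehot) / npix
            # soft-Dice gradient: dL/dp_c per pixel, then softmax jacobian
            gp = np.zeros_like(p)
            denom = psum + tsum + eps
            for cls in fg:
                t = onehot[:, cls]
                num = 2.0 * t * denom[cls] - (2.0 * inter[cls] + eps)
                gp[:, cls] = -(num / denom[cls] ** 2) / len(fg)
            dot = (gp * p).sum(axis=1, keepdims=True)
            dz = dz + p * (gp - dot)
            logits._accumulate(gout.reshape(()) * dz)

        return backward

    return _make(np.array(loss, dtype=z.dtype), (logits,), factory)


def dice_report_from_cases(case_dices: list[dict[int, float]]) -> DiceReport:
    """Average per-case, per-class DSCs: cases first, then classes."""
    if not case_dices:
        return DiceReport(per_class={}, mean=float("nan"), n_cases=0)
    classes = sorted(case_dices[0])
    per_class = {
        cls: float(np.mean([d[cls] for d in case_dices])) for cls in classes
    }
    mean = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return DiceReport(per_class=per_class, mean=mean, n_cases=len(case_dices))


def case_dice(pred: np.ndarray, ref: np.ndarray, num_classes: int) -> dict[int, float]:
    """Per-foreground-class DSC of one predicted/reference label map pair."""
    return {
        cls: dice_coefficient(pred == cls, ref == cls)
        for cls in range(1, num_classes)
    }


def evaluate_dataset(model, samples, batch_size: int = 8) -> DiceReport:
    """Per-class DSC of argmax predictions, averaged case-then-class.

    ``model`` is a built network (or anything with ``forward``/``cfg``);
    ``samples`` an iterable of objects with ``image`` (C, H, W) and
    ``label`` (H, W) arrays.
    """
    from .nn import no_grad

    c = model.cfg.num_classes
    case_dices = []
    records = []
    samples = list(samples)
    with no_grad():
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            shapes = {s.image.shape for s in chunk}
            if len(shapes) == 1:
                batch = np.stack([s.image for s in chunk])
                preds = np.argmax(model.forward(batch).data, axis=1)
            else:
                preds = [
                    np.argmax(model.forward(s.image[None]).data, axis=1)[0]
                    for s in chunk
                ]
            for s, pred in zip(chunk, preds):
                ref = np.asarray(s.label)
                if ref.max() >= c:
                    raise ValueError(
                        f"label {ref.max()} exceeds model classes ({c})"
                    )
                d = case_dice(pred, ref, c)
                case_dices.append(d)
                for cls, v in d.items():
                    records.append(
                        {"case_id": getattr(s, "case_id", str(start)),
                         "class": cls, "dsc": v}
                    )
    report = dice_report_from_cases(case_dices)
    report_frame = pd.DataFrame.from_records(records)
    report.frame = report_frame  # per-case per-class rows for CSV export
    return report
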