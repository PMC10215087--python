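"""Dice metric and combined cross-entropy + soft-Dice loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _reference import ref_dice_ce
from rkseg import ArchitectureConfig, build_rkseg
from rkseg.losses import (
    case_dice,
    dice_ce_loss,
    dice_coefficient,
    dice_report_from_cases,
    evaluate_dataset,
)
from rkseg.nn import Tensor
from rkseg.synth import SegmentationSample


class TestDiceCoefficient:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True          # |A| = 4
        b[0, 2:] = True          # overlap 2
        b[1, :2] = True          # |B| = 4
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3), bool)
        assert dice_coefficient(empty, empty) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        assert dice_coefficient(a, b) == dice_coefficient(b, a)
        perm = rng.permutation(a.size)
        ap = a.ravel()[perm].reshape(a.shape)
        bp = b.ravel()[perm].reshape(b.shape)
        assert dice_coefficient(a, b) == pytest.approx(dice_coefficient(ap, bp))


class TestDiceCELoss:
    def test_uniform_logits_give_log2_cross_entropy(self):
        logits = Tensor(np.zeros((1, 2, 4, 4)))
        labels = np.tile([[0, 1], [1, 0]], (2, 2))[None]
        loss = float(dice_ce_loss(logits, labels).data)
        # CE = ln 2 exactly; soft Dice of the p=0.5 foreground map is
        # (2*4 + eps)/(8 + 8 + eps) = 0.5, so the Dice term adds 0.5
        assert loss == pytest.approx(np.log(2) + 0.5, rel=1e-6)

    def test_confident_correct_prediction_saturates_to_zero(self):
        labels = np.array([[[0, 1], [1, 0]]])
        logits = np.full((1, 2, 2, 2), -50.0)
        for i in range(2):
            for j in range(2):
                logits[0, labels[0, i, j], i, j] = 50.0
        loss = float(dice_ce_loss(Tensor(logits), labels).data)
        assert loss == pytest.approx(0.0, abs=1e-4)

    def test_matches_straight_line_reference(self, rng):
        logits = rng.normal(size=(2, 3, 4, 4))
        labels = rng.integers(0, 3, size=(2, 4, 4))
        got = float(dice_ce_loss(Tensor(logits), labels).data)
        assert got == pytest.approx(ref_dice_ce(logits, labels), rel=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(1, 3, 3, 3))
        labels = rng.integers(0, 3, size=(1, 3, 3))
        t = Tensor(logits.copy(), requires_grad=True)
        dice_ce_loss(t, labels).backward()
        eps = 1e-6
        for _ in range(10):
            i = tuple(rng.integers(0, s) for s in logits.shape)
            orig = logits[i]
            logits[i] = orig + eps
            fp = float(dice_ce_loss(Tensor(logits), labels).data)
            logits[i] = orig - eps
            fm = float(dice_ce_loss(Tensor(logits), labels).data)
            logits[i] = orig
            num = (fp - fm) / (2 * eps)
            assert t.grad[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_one_hot_dice_term_matches_hard_dice(self, rng):
        # near-one-hot probabilities: soft Dice ~ hard Dice of the argmax
        labels = rng.integers(0, 2, size=(1, 8, 8))
        pred = rng.integers(0, 2, size=(1, 8, 8))
        logits = np.where(
            (np.arange(2)[None, :, None, None] == pred[:, None]), 10.0, -10.0
        )
        loss = float(dice_ce_loss(Tensor(logits), labels).data)
        hard = dice_coefficient(pred[0] == 1, labels[0] == 1)
        # wrong pixels each contribute CE of the logit margin (20); correct
        # pixels ~0; soft Dice of a near-one-hot map equals the hard DSC
        expected = float(np.mean(pred != labels)) * 20.0 + (1.0 - hard)
        assert loss == pytest.approx(expected, rel=1e-3)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="label values"):
            dice_ce_loss(Tensor(np.zeros((1, 2, 2, 2))),
                         np.full((1, 2, 2), 5))


def _sample(image, label, case_id="c0"):
    return SegmentationSample(image=np.asarray(image, np.float32),
                              label=np.asarray(label, np.uint8),
                              case_id=case_id)


class _OracleModel:
    """Test double whose logits always predict a fixed label map."""

    def __init__(self, maps, num_classes):
        self.maps = {i: m for i, m in enumerate(maps)}
        self._count = 0

        class _Cfg:
            pass

        self.cfg = _Cfg()
        self.cfg.num_classes = num_classes

    def forward(self, batch):
        n, _, h, w = batch.shape
        c = self.cfg.num_classes
        out = np.full((n, c, h, w), -10.0)
        for b in range(n):
            m = self.maps[self._count]
            self._count += 1
            for cls in range(c):
                out[b, cls][m == cls] = 10.0
        return Tensor(out)


class TestEvaluateDataset:
    def test_perfect_predictions_score_one(self):
        labels = [np.array([[0, 1], [1, 2]]), np.array([[2, 2], [0, 1]])]
        samples = [_sample(np.zeros((1, 2, 2)), lab, f"c{i}")
                   for i, lab in enumerate(labels)]
        model = _OracleModel(labels, num_classes=3)
        report = evaluate_dataset(model, samples, batch_size=1)
        assert report.per_class == {1: 1.0, 2: 1.0}
        assert report.mean == 1.0
        assert report.n_cases == 2

    def test_all_background_predictions_score_zero(self):
        ref = np.array([[0, 1], [1, 0]])
        samples = [_sample(np.zeros((1, 2, 2)), ref)]
        model = _OracleModel([np.zeros((2, 2), int)], num_classes=2)
        report = evaluate_dataset(model, samples, batch_size=1)
        assert report.per_class == {1: 0.0}

    def test_two_case_toy_set_matches_hand_computation(self):
        # case 1: pred=|A|=4 vs ref |B|=4, overlap 2 -> DSC 0.5
        # case 2: perfect -> DSC 1.0; case-then-class mean = 0.75
        ref1 = np.zeros((4, 4), int)
        ref1[0, 2:] = 1
        ref1[1, :2] = 1
        pred1 = np.zeros((4, 4), int)
        pred1[0, :] = 1
        ref2 = np.zeros((4, 4), int)
        ref2[2:, 2:] = 1
        samples = [_sample(np.zeros((1, 4, 4)), ref1, "a"),
                   _sample(np.zeros((1, 4, 4)), ref2, "b")]
        model = _OracleModel([pred1, ref2], num_classes=2)
        report = evaluate_dataset(model, samples, batch_size=1)
        assert report.per_class[1] == pytest.approx(0.75)
        assert report.mean == pytest.approx(0.75)
        assert set(report.frame.columns) == {"case_id", "class", "dsc"}

    def test_label_exceeding_model_classes_rejected(self):
        samples = [_sample(np.zeros((1, 2, 2)), np.full((2, 2), 3))]
        model = _OracleModel([np.zeros((2, 2), int)], num_classes=2)
        with pytest.raises(ValueError, match="exceeds model classes"):
            evaluate_dataset(model, samples)

    def test_case_then_class_aggregation(self):
        cases = [{1: 1.0, 2: 0.0}, {1: 0.5, 2: 1.0}]
        rep = dice_report_from_cases(cases)
        assert rep.per_class == {1: 0.75, 2: 0.5}
        assert rep.mean == pytest.approx(0.625)

    def test_case_dice_covers_foreground_classes_only(self):
        pred = np.array([[0, 1], [2, 0]])
        ref = np.array([[0, 1], [1, 0]])
        d = case_dice(pred, ref, num_classes=3)
        assert set(d) == {1, 2}
        assert d[1] == pytest.approx(2 / 3)
        assert d[2] == 0.0

    def test_real_model_end_to_end(self, rng):
        net = build_rkseg(ArchitectureConfig("L", "E", 2, 4, 1, 2))
        samples = [_sample(rng.normal(size=(1, 16, 16)),
                           rng.integers(0, 2, (16, 16)), f"c{i}")
                   for i in range(3)]
        report = evaluate_dataset(net, samples)
        assert report.n_cases == 3
        assert 0.0 <= report.mean <= 1.0
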