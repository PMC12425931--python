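"""Segmentation metrics against brute-force per-pixel oracles, plus the
paired t-test on per-image scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdwcnet.errors import DegenerateInputError, InvalidInputError
from mdwcnet.metrics import (ConfusionCounts, confusion_counts, dice,
                             evaluate_dataset, gpa, image_metrics, miou,
                             paired_t_test, sensitivity)


def brute_force_counts(pred, gt):
    """Exhaustive per-pixel loop; the independent reference for all metrics."""
    tp = fp = tn = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p == 1 and g == 1:
            tp += 1
        elif p == 1 and g == 0:
            fp += 1
        elif p == 0 and g == 0:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestConfusionCounts:
    def test_pure_cases(self):
        ones = np.ones((4, 4), dtype=np.uint8)
        zeros = np.zeros((4, 4), dtype=np.uint8)
        c = confusion_counts(ones, ones)
        assert (c.tp, c.fp, c.tn, c.fn) == (16, 0, 0, 0)
        c = confusion_counts(ones, zeros)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 16, 0, 0)

    def test_matches_pixel_loop(self, rng):
        for _ in range(20):
            pred = (rng.random((4, 4)) < 0.5).astype(np.uint8)
            gt = (rng.random((4, 4)) < 0.5).astype(np.uint8)
            assert confusion_counts(pred, gt) == brute_force_counts(pred, gt)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(InvalidInputError):
            confusion_counts(np.full((2, 2), 2), np.zeros((2, 2)))


class TestFormulas:
    def test_worked_examples(self):
        assert gpa(ConfusionCounts(16, 0, 0, 0)) == 1.0
        assert gpa(ConfusionCounts(tp=3, tn=9, fp=2, fn=2)) == 0.75
        assert dice(ConfusionCounts(tp=3, fp=1, tn=0, fn=1)) == 0.75
        assert dice(ConfusionCounts(5, 0, 11, 0)) == 1.0
        assert dice(ConfusionCounts(0, 3, 10, 3)) == 0.0  # disjoint masks
        assert sensitivity(ConfusionCounts(tp=3, fp=0, tn=0, fn=1)) == 0.75
        fg = ConfusionCounts(tp=1, fp=1, tn=0, fn=0)  # IoU 0.5
        bg = ConfusionCounts(tp=9, fp=0, tn=0, fn=1)  # IoU 0.9
        assert np.isclose(miou([fg, bg]), 0.7)

    def test_degenerate_conventions(self):
        assert dice(ConfusionCounts(0, 0, 16, 0)) == 1.0  # both masks empty
        assert miou([ConfusionCounts(0, 0, 16, 0)]) == 1.0
        with pytest.raises(InvalidInputError):
            sensitivity(ConfusionCounts(0, 2, 14, 0))  # empty reference
        with pytest.raises(InvalidInputError):
            gpa(ConfusionCounts(0, 0, 0, 0))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_properties_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((8, 8)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        gt = (rng.random((8, 8)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        m = image_metrics(pred, gt)
        mf = image_metrics(pred[:, ::-1], gt[:, ::-1])  # joint horizontal flip
        assert m == mf
        assert 0.0 <= m["dice"] <= 1.0 and 0.0 <= m["gpa"] <= 1.0
        c = confusion_counts(pred, gt)
        # Dice and foreground IoU are algebraically linked
        fg_iou = 1.0 if c.tp + c.fp + c.fn == 0 else c.tp / (c.tp + c.fp + c.fn)
        assert np.isclose(m["dice"], 2 * fg_iou / (1 + fg_iou))
        # dice == 1 iff no disagreement with some overlap
        assert (m["dice"] == 1.0) == (c.fp == 0 and c.fn == 0)
        # purity: recomputation is bit-identical
        assert image_metrics(pred, gt) == m

    def test_miou_matches_set_operations_oracle(self, rng):
        for _ in range(10):
            pred = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            gt = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            ious = []
            for cls in (0, 1):
                p = {tuple(i) for i in np.argwhere(pred == cls)}
                g = {tuple(i) for i in np.argwhere(gt == cls)}
                ious.append(1.0 if not p | g else len(p & g) / len(p | g))
            c = confusion_counts(pred, gt)
            bg = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
            assert np.isclose(miou([bg, c]), np.mean(ious), atol=1e-12)


class TestDatasetAggregation:
    def test_perfect_single_image(self):
        m = np.ones((4, 4), dtype=np.uint8)
        rep = evaluate_dataset([m], [m])
        assert all(rep.mean[k] == 100.0 for k in rep.METRICS)
        assert all(rep.std[k] == 0.0 for k in rep.METRICS)

    def test_mean_and_sample_std(self):
        gt = np.zeros((2, 10), dtype=np.uint8)
        gt[:, :6] = 1  # 12 foreground pixels
        perfect = gt.copy()
        partial = gt.copy()
        partial[:, 4:6] = 0  # tp=8, fn=4 -> dice 16/20 = 0.8
        rep = evaluate_dataset([perfect, partial], [gt, gt])
        assert np.isclose(rep.mean["dice"], 90.0)
        assert np.isclose(rep.std["dice"], np.std([100.0, 80.0], ddof=1))

    def test_matches_per_image_loop(self, rng):
        preds = [(rng.random((6, 6)) < 0.5).astype(np.uint8) for _ in range(5)]
        gts = [np.clip(p + (rng.random((6, 6)) < 0.2), 0, 1).astype(np.uint8) for p in preds]
        rep = evaluate_dataset(preds, gts)
        dices = [image_metrics(p, g)["dice"] * 100 for p, g in zip(preds, gts)]
        assert np.isclose(rep.mean["dice"], np.mean(dices))

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            evaluate_dataset([], [])


class TestPairedTTest:
    def test_identical_vectors_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_textbook_hand_computation(self):
        # differences {1,1,1,-1}: mean 0.5, sd 1, t = 0.5/(1/2) = 1 on 3 df
        from scipy import stats

        p = paired_t_test([2.0, 2.0, 2.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert np.isclose(p, 2 * stats.t.sf(1.0, df=3), atol=1e-12)

    def test_large_shift_is_significant(self, rng):
        base = rng.normal(0.8, 0.01, size=20)
        shifted = base + 0.1 + rng.normal(0.0, 0.01, size=20)  # effect >> noise
        assert paired_t_test(shifted, base) < 0.05
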