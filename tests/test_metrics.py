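"""Metric battery vs hand arithmetic and brute-force oracles."""

import numpy as np
import pytest

from lessnet import metrics as M

import oracles


def random_pair(rng, p_fg=0.4, size=8):
    truth = (rng.random((size, size)) < p_fg).astype(np.uint8)
    pred = (rng.random((size, size)) < p_fg).astype(np.uint8)
    return pred, truth


class TestHandExamples:
    def test_confusion_enumerated(self):
        truth = np.array([0] * 6 + [1] * 4).reshape(2, 5)
        pred = truth.copy().reshape(-1)
        pred[6] = 0   # one foreground pixel lost
        pred[0] = 1   # one background pixel gained
        cm = M.confusion(pred.reshape(2, 5), truth)
        assert cm.tolist() == [[5, 1], [1, 3]]
        assert cm.sum() == truth.size

    def test_confusion_perfect_is_diagonal(self):
        t = np.array([[0, 1], [1, 0]])
        cm = M.confusion(t, t)
        assert cm[0, 1] == cm[1, 0] == 0

    def test_confusion_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            M.confusion(np.array([[2]]), np.array([[0]]), n_classes=2)

    def test_dice_cases(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[:2, :2] = 1
        b = np.zeros((4, 4), dtype=np.uint8)
        b[1:3, :2] = 1  # |X|=4, |Y|=4, overlap 2
        assert M.dice(a, b) == pytest.approx(0.5)
        assert M.dice(a, a) == 1.0
        disjoint = np.zeros_like(a)
        disjoint[3, 3] = 1
        assert M.dice(a, disjoint) == 0.0
        assert M.dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_miou_hand_matrix(self):
        ious, mean, _ = M.miou(np.array([[5, 1], [1, 3]]))
        assert ious[0] == pytest.approx(5 / 7)
        assert ious[1] == pytest.approx(3 / 5)
        assert mean == pytest.approx((5 / 7 + 3 / 5) / 2)

    def test_miou_absent_class_convention(self):
        ious, mean, flags = M.miou(np.array([[10, 0], [0, 0]]))
        assert ious[1] == 1.0
        assert flags

    def test_mrecall_and_accuracy_hand_matrix(self):
        mrec, acc8, pix, _ = M.mrecall_and_accuracy(np.array([[5, 1], [1, 3]]))
        assert mrec == pytest.approx(19 / 24)
        # 10 pixels, 8 correct: each error once as FP and once as FN
        assert acc8 == pytest.approx(8 / 12)
        assert pix == pytest.approx(0.8)

    def test_hd95_cases(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b = np.zeros((8, 8), dtype=np.uint8)
        b[3, 4] = 1
        assert M.hd95(a, b) == pytest.approx(5.0)  # 3-4-5 triangle
        assert M.hd95(a, a) == 0.0
        seg1 = np.zeros((8, 8), dtype=np.uint8)
        seg1[2, 1:6] = 1
        seg2 = np.zeros((8, 8), dtype=np.uint8)
        seg2[4, 1:6] = 1  # parallel segments offset by 2
        assert M.hd95(seg1, seg2) == pytest.approx(2.0)
        assert M.hd95(np.zeros((4, 4)), np.zeros((4, 4))) == 0.0
        assert np.isinf(M.hd95(a, np.zeros((8, 8))))

    def test_hd95_spacing_scales_to_physical_units(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b = np.zeros((8, 8), dtype=np.uint8)
        b[3, 4] = 1
        assert M.hd95(a, b, spacing=0.5) == pytest.approx(2.5)

    def test_ece_cases(self):
        # all pixels confidence 0.9 on class 1, half correct
        probs = np.zeros((2, 2, 2))
        probs[1] = 0.9
        probs[0] = 0.1
        truth = np.array([[1, 1], [0, 0]])
        assert M.ece(probs, truth, n_bins=10) == pytest.approx(0.4)
        # perfectly calibrated single bin: confidence 0.8, 80% correct
        big = np.zeros((2, 1, 5))
        big[1] = 0.8
        big[0] = 0.2
        tb = np.array([[1, 1, 1, 1, 0]])
        assert M.ece(big, tb, n_bins=10) == pytest.approx(0.0)
        # confident and always right
        onehot = np.zeros((2, 2, 2))
        onehot[1] = 1.0
        assert M.ece(onehot, np.ones((2, 2), dtype=int), n_bins=15) == 0.0

    def test_entropy_cases(self):
        p = np.zeros((2, 1, 3))
        p[:, 0, 0] = [1.0, 0.0]
        p[:, 0, 1] = [0.5, 0.5]
        p[:, 0, 2] = [0.9, 0.1]
        e = M.entropy_map(p)
        assert e[0, 0] == 0.0
        assert e[0, 1] == pytest.approx(np.log(2))
        assert e[0, 2] == pytest.approx(-0.9 * np.log(0.9) - 0.1 * np.log(0.1))


class TestOracleEquivalence:
    def test_all_metrics_match_bruteforce_on_random_pairs(self, rng):
        """200 random 8x8 mask/probability pairs, agreement to 1e-9."""
        for trial in range(200):
            pred, truth = random_pair(rng, p_fg=rng.uniform(0.0, 0.8))
            cm = M.confusion(pred, truth)
            assert np.array_equal(cm, oracles.confusion_loops(pred, truth, 2))
            assert abs(M.dice(pred, truth) - oracles.dice_loops(pred, truth)) < 1e-9
            ious, mean, _ = M.miou(cm)
            o_ious = oracles.iou_per_class_loops(cm)
            assert np.allclose(ious, o_ious, atol=1e-9)
            assert abs(mean - np.mean(o_ious)) < 1e-9
            mrec, acc8, pix, _ = M.mrecall_and_accuracy(cm)
            o_mrec = oracles.mrecall_loops(cm)
            if np.isnan(o_mrec):
                assert np.isnan(mrec)
            else:
                assert abs(mrec - o_mrec) < 1e-9
            assert abs(acc8 - oracles.accuracy_eq8_loops(cm)) < 1e-9
            assert abs(pix - oracles.pixel_accuracy_loops(cm)) < 1e-9
            h = M.hd95(pred, truth)
            ho = oracles.hd95_loops(pred, truth)
            assert (np.isinf(h) and np.isinf(ho)) or abs(h - ho) < 1e-9
            raw = rng.random((2, 8, 8))
            probs = raw / raw.sum(axis=0, keepdims=True)
            assert abs(M.ece(probs, truth, 15) - oracles.ece_loops(probs, truth, 15)) < 1e-9
            assert np.allclose(M.entropy_map(probs), oracles.entropy_loops(probs), atol=1e-9)


class TestProperties:
    def test_f1_equals_foreground_dice(self, rng):
        for _ in range(50):
            pred, truth = random_pair(rng, p_fg=rng.uniform(0.1, 0.9))
            cm = M.confusion(pred, truth)
            assert M.f1_from_confusion(cm) == pytest.approx(M.dice(pred, truth), abs=1e-12)

    def test_confusion_accumulates_over_tiles(self, rng):
        pred, truth = random_pair(rng, size=16)
        whole = M.confusion(pred, truth)
        tiled = sum(M.confusion(pred[i:i + 8, j:j + 8], truth[i:i + 8, j:j + 8])
                    for i in (0, 8) for j in (0, 8))
        assert np.array_equal(whole, tiled)

    def test_metric_ranges(self, rng):
        for _ in range(20):
            pred, truth = random_pair(rng)
            raw = rng.random((2, 8, 8))
            probs = raw / raw.sum(axis=0, keepdims=True)
            assert 0.0 <= M.dice(pred, truth) <= 1.0
            _, mean, _ = M.miou(M.confusion(pred, truth))
            assert 0.0 <= mean <= 1.0
            assert 0.0 <= M.ece(probs, truth, 15) <= 1.0
            e = M.entropy_map(probs)
            assert (e >= -1e-12).all() and (e <= np.log(2) + 1e-12).all()

    def test_report_aggregation(self, rng):
        preds, truths, probs = [], [], []
        for _ in range(5):
            p, t = random_pair(rng)
            raw = rng.random((2, 8, 8))
            pr = raw / raw.sum(axis=0, keepdims=True)
            preds.append(p); truths.append(t); probs.append(pr)
        rep = M.evaluate_predictions(preds, truths, probs=probs)
        assert 0.0 <= rep.miou <= 1.0
        assert 0.0 <= rep.ece <= 1.0
        assert rep.per_class_iou[0] >= 0.0

    def test_perfect_prediction_report(self, tiny_dataset):
        masks = [s.mask for s in tiny_dataset[:4]]
        probs = [np.stack([1.0 - m, m.astype(float)]) for m in masks]
        rep = M.evaluate_predictions(masks, masks, probs=probs)
        assert rep.dice == 1.0 and rep.miou == 1.0 and rep.mrecall == 1.0
        assert rep.hd95 == 0.0 and rep.ece == pytest.approx(0.0)
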