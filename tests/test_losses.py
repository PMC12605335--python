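"""Objective functions: hand-computed values, invariants, gradient sanity."""

import numpy as np
import pytest

from lessnet.losses import (LossWeights, lambda_schedule, supervised_loss,
                            total_loss, triplet_consistency_loss)
from lessnet.nn import Tensor
from lessnet.nn import functional as F


def probs_to_logits(p):
    return Tensor(np.log(np.asarray(p, dtype=np.float64)))


class TestSupervisedLoss:
    def test_uniform_prediction_gives_ln2(self):
        logits = Tensor(np.zeros((1, 2, 4, 4)))
        mask = np.zeros((1, 4, 4), dtype=int)
        assert supervised_loss(logits, mask).item() == pytest.approx(np.log(2), rel=1e-6)

    def test_perfect_prediction_approaches_zero(self):
        mask = np.array([[[0, 1], [1, 0]]])
        big = 50.0
        logits = np.zeros((1, 2, 2, 2))
        logits[0, 1] = big * mask[0]
        logits[0, 0] = big * (1 - mask[0])
        assert supervised_loss(Tensor(logits), mask).item() < 1e-8

    def test_two_pixel_hand_example(self):
        # true classes (0, 1), predicted true-class probabilities (0.8, 0.4)
        p = np.array([[[[0.8, 0.6]], [[0.2, 0.4]]]])  # (1, 2, 1, 2)
        mask = np.array([[[0, 1]]])
        expected = -(np.log(0.8) + np.log(0.4)) / 2
        assert supervised_loss(probs_to_logits(p), mask).item() == pytest.approx(expected, rel=1e-9)

    def test_rejects_nonbinary_mask(self):
        with pytest.raises(ValueError):
            supervised_loss(Tensor(np.zeros((1, 2, 2, 2))), np.full((1, 2, 2), 2))


class TestTripletConsistency:
    def hand_maps(self):
        p_o = Tensor(np.array([[[[0.5]], [[0.5]]]]))
        p_w = Tensor(np.array([[[[1.0]], [[0.0]]]]))
        p_s = Tensor(np.array([[[[0.0]], [[1.0]]]]))
        return p_o, p_w, p_s

    def test_hand_example_sum_form(self):
        p_o, p_w, p_s = self.hand_maps()
        w = LossWeights(alpha=1, beta=1, gamma=1)
        val = triplet_consistency_loss(p_o, p_w, p_s, w, reduction="sum").item()
        assert val == pytest.approx(0.5 + 0.5 + 2.0)

    def test_identical_maps_give_zero(self):
        p = Tensor(np.random.default_rng(0).random((2, 2, 3, 3)))
        assert triplet_consistency_loss(p, p, p, LossWeights()).item() == 0.0

    def test_zero_weights_annihilate(self):
        rng = np.random.default_rng(1)
        maps = [Tensor(rng.random((1, 2, 3, 3))) for _ in range(3)]
        w = LossWeights(alpha=0, beta=0, gamma=0)
        assert triplet_consistency_loss(*maps, w).item() == 0.0

    def test_linearity_in_weights(self, rng):
        maps = [Tensor(rng.random((2, 2, 4, 4))) for _ in range(3)]
        v1 = triplet_consistency_loss(*maps, LossWeights(alpha=1, beta=1, gamma=1)).item()
        v2 = triplet_consistency_loss(*maps, LossWeights(alpha=2, beta=2, gamma=2)).item()
        assert v2 == pytest.approx(2 * v1, rel=1e-6)

    def test_swap_symmetry(self, rng):
        p_o, p_w, p_s = [Tensor(rng.random((1, 2, 4, 4))) for _ in range(3)]
        a = triplet_consistency_loss(p_o, p_w, p_s,
                                     LossWeights(alpha=1, beta=2, gamma=3)).item()
        b = triplet_consistency_loss(p_o, p_s, p_w,
                                     LossWeights(alpha=2, beta=1, gamma=3)).item()
        assert a == pytest.approx(b, rel=1e-7)

    def test_nonnegative_and_zero_iff_coincident(self, rng):
        w = LossWeights(alpha=1, beta=1, gamma=1)
        for _ in range(10):
            maps = [Tensor(rng.random((1, 2, 3, 3))) for _ in range(3)]
            assert triplet_consistency_loss(*maps, w).item() > 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_consistency_loss(Tensor(np.zeros((1, 2, 2, 2))),
                                     Tensor(np.zeros((1, 2, 2, 2))),
                                     Tensor(np.zeros((1, 2, 4, 4))), LossWeights())


class TestTotalAndSchedule:
    def test_total_combination(self):
        assert total_loss(0.5, 3.0, 0.1) == pytest.approx(0.8)
        assert total_loss(0.7, 5.0, 0.0) == pytest.approx(0.7)
        assert total_loss(0.7, 0.0, 2.5) == pytest.approx(0.7)

    def test_ramp_start_plateau_monotone(self):
        w = LossWeights(lambda_u=2.0, ramp_epochs=10)
        assert lambda_schedule(0, w) < 0.01 * w.lambda_u
        assert lambda_schedule(10, w) == w.lambda_u
        assert lambda_schedule(25, w) == w.lambda_u
        seq = [lambda_schedule(e, w) for e in range(11)]
        assert all(b >= a for a, b in zip(seq, seq[1:]))

    def test_zero_ramp_is_constant(self):
        w = LossWeights(lambda_u=1.5, ramp_epochs=0)
        assert lambda_schedule(0, w) == 1.5


class TestGradientSanity:
    def test_total_loss_gradient_matches_finite_difference(self):
        """One-parameter toy model: logits are w * (fixed patterns); the
        analytic d(total)/dw must match central differences to 1e-4."""
        rng = np.random.default_rng(3)
        base = [rng.normal(size=(1, 2, 3, 3)) for _ in range(4)]
        mask = rng.integers(0, 2, size=(1, 3, 3))
        lam = 0.7
        weights = LossWeights(alpha=1.0, beta=0.5, gamma=2.0)

        def loss_at(wv, need_grad=False):
            w = Tensor(np.array(wv, dtype=np.float64), requires_grad=need_grad)
            sup = supervised_loss(w * Tensor(base[0]), mask)
            views = [F.softmax(w * Tensor(b), axis=1) for b in base[1:]]
            tot = total_loss(sup, triplet_consistency_loss(*views, weights), lam)
            return w, tot

        w, tot = loss_at(1.3, need_grad=True)
        tot.backward()
        eps = 1e-6
        num = (loss_at(1.3 + eps)[1].item() - loss_at(1.3 - eps)[1].item()) / (2 * eps)
        assert w.grad.item() == pytest.approx(num, rel=1e-4)
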