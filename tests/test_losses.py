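"""Loss oracles: hand-computed toy instances, closed forms, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smfnet.autodiff as ad
from smfnet.autodiff import Tensor
from smfnet.losses import (DEFAULT_LAMBDAS, adversarial_generator_loss,
                           consistency_error, consistency_loss,
                           cross_entropy_loss, dice_loss, discriminator_loss,
                           stabilization_loss, supervised_loss,
                           total_student_loss)


def _probs_from(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


def _one_hot_probs(target, k):
    b = target.shape[0]
    p = np.zeros((b, k) + target.shape[1:], dtype=np.float32)
    for c in range(k):
        p[:, c] = target == c
    return Tensor(p)


class TestDiceLoss:
    def test_perfect_prediction_scores_zero(self):
        target = np.array([[[0, 1], [2, 1]]])
        assert float(dice_loss(_one_hot_probs(target, 3), target).data) \
            == pytest.approx(0.0, abs=1e-5)

    def test_hand_worked_single_class_toy(self):
        """p = [1,1,0,0], y = [0,1,1,0] -> Dice 2*1/(2+2) = 0.5, loss 0.5."""
        p = np.zeros((1, 2, 2, 2), dtype=np.float32)
        p[0, 1] = [[1, 1], [0, 0]]
        p[0, 0] = 1 - p[0, 1]
        y = np.array([[[0, 1], [1, 0]]])
        # class 1: dice 0.5; class 0 (complement): also overlap 1 of 2+2
        loss = float(dice_loss(_probs_from(p.copy()), y).data)
        assert loss == pytest.approx(0.5, abs=1e-5)

    def test_class_absent_from_target_gets_zero_dice(self):
        p = np.zeros((1, 3, 2, 2), dtype=np.float32)
        p[0, 2] = 1.0  # predict lesion everywhere
        y = np.zeros((1, 2, 2), dtype=np.int64)  # all background
        # class 2: pred 4 px, truth 0 -> dice ~0; class 0: 0 pred, 4 truth
        # -> ~0; class 1 both empty -> smoothing gives 1
        loss = float(dice_loss(_probs_from(p), y).data)
        assert loss == pytest.approx(1 - 1 / 3, abs=1e-4)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dice_loss(Tensor(np.zeros((0, 3, 2, 2), np.float32)),
                      np.zeros((0, 2, 2), np.int64))


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[[0, 1], [2, 0]]])
        assert float(cross_entropy_loss(_one_hot_probs(y, 3), y).data) \
            == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("p_true,expected", [(1 / 3, np.log(3)),
                                                 (0.5, np.log(2))])
    def test_uniform_confidence_closed_forms(self, p_true, expected):
        b, k = 2, 3
        probs = np.full((b, k, 4, 4), (1 - p_true) / (k - 1), dtype=np.float32)
        y = np.ones((b, 4, 4), dtype=np.int64)
        probs[:, 1] = p_true
        assert float(cross_entropy_loss(_probs_from(probs), y).data) \
            == pytest.approx(expected, rel=1e-5)


class TestSupervisedLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[[1, 0], [2, 2]]])
        assert float(supervised_loss(_one_hot_probs(y, 3), y).data) \
            == pytest.approx(0.0, abs=1e-5)

    def test_equals_mean_of_components(self):
        rng = np.random.default_rng(0)
        p = rng.random((2, 3, 4, 4)).astype(np.float32)
        p /= p.sum(axis=1, keepdims=True)
        y = rng.integers(0, 3, (2, 4, 4))
        total = float(supervised_loss(_probs_from(p), y).data)
        parts = (float(cross_entropy_loss(_probs_from(p), y).data)
                 + float(dice_loss(_probs_from(p), y).data)) / 2
        assert total == pytest.approx(parts, rel=1e-6)

    def test_similarity_flag_swaps_dice_direction(self):
        rng = np.random.default_rng(1)
        p = rng.random((1, 3, 4, 4)).astype(np.float32)
        p /= p.sum(axis=1, keepdims=True)
        y = rng.integers(0, 3, (1, 4, 4))
        a = float(supervised_loss(_probs_from(p), y).data)
        b = float(supervised_loss(_probs_from(p), y,
                                  eq15_dice_as_similarity=True).data)
        d = float(dice_loss(_probs_from(p), y).data)
        assert b - a == pytest.approx((1 - 2 * d) / 2, abs=1e-5)


class TestConsistency:
    def test_identical_maps_give_zero_error(self):
        p = _probs_from(np.random.default_rng(0).random((1, 3, 4, 4)))
        eps = consistency_error(p, Tensor(p.data.copy()))
        assert float(np.abs(eps.data).max()) == 0.0

    def test_single_pixel_difference_squares(self):
        a = np.zeros((1, 2, 2, 2), dtype=np.float32)
        b = a.copy()
        b[0, 1, 0, 1] = 0.1
        eps = consistency_error(_probs_from(a), _probs_from(b)).data
        assert eps[0, 0, 1] == pytest.approx(0.01, rel=1e-5)
        assert eps.sum() == pytest.approx(0.01, rel=1e-5)

    def test_error_is_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = (rng.random((1, 3, 4, 4)).astype(np.float32) for _ in "ab")
        e1 = consistency_error(_probs_from(a), _probs_from(b)).data
        e2 = consistency_error(_probs_from(b), _probs_from(a)).data
        np.testing.assert_allclose(e1, e2, rtol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            consistency_error(Tensor(np.zeros((1, 3, 4, 4), np.float32)),
                              Tensor(np.zeros((1, 3, 4, 2), np.float32)))

    def test_loss_is_spatial_mean(self):
        m = np.array([[[0.04, 0.0], [0.0, 0.0]]], dtype=np.float32)
        assert float(consistency_loss(Tensor(m)).data) \
            == pytest.approx(0.01, rel=1e-6)
        assert float(consistency_loss(Tensor(3 * m)).data) \
            == pytest.approx(0.03, rel=1e-6)


class TestStabilization:
    def _maps(self, b=2, n=4):
        rng = np.random.default_rng(3)
        return (rng.random((b, n, n)), rng.random((b, n, n)),
                Tensor(rng.random((b, n, n)).astype(np.float32)))

    def test_identical_student_outputs_zero_loss(self):
        eps_a, eps_b, _ = self._maps()
        zero = Tensor(np.zeros((2, 4, 4), np.float32))
        for ra, rb in ((1, 1), (1, 0), (0, 0)):
            loss = stabilization_loss(eps_a, eps_b, zero,
                                      np.full(2, ra), np.full(2, rb))
            assert float(loss.data) == 0.0

    def test_both_stable_uses_indicator_mean(self):
        eps_a = np.zeros((1, 2, 2))
        eps_b = np.ones((1, 2, 2))       # eps_a < eps_b everywhere
        mse = Tensor(np.full((1, 2, 2), 0.5, np.float32))
        loss = stabilization_loss(eps_a, eps_b, mse, np.ones(1, int),
                                  np.ones(1, int))
        assert float(loss.data) == pytest.approx(0.5)
        flipped = stabilization_loss(eps_a, eps_b, mse, np.ones(1, int),
                                     np.ones(1, int), flip_indicator=True)
        assert float(flipped.data) == 0.0

    def test_unstable_samples_gated_by_r_a(self):
        eps_a, eps_b, mse = self._maps()
        zero_r = np.zeros(2, int)
        assert float(stabilization_loss(eps_a, eps_b, mse, zero_r,
                                        zero_r).data) == 0.0
        full = stabilization_loss(eps_a, eps_b, mse, np.ones(2, int), zero_r)
        assert float(full.data) == pytest.approx(float(mse.data.mean()),
                                                 rel=1e-5)


class TestAdversarial:
    def test_confident_real_scores_zero_generator_loss(self):
        assert float(adversarial_generator_loss(
            Tensor(np.ones(4, np.float32))).data) == pytest.approx(0.0, abs=1e-5)

    def test_half_confidence_is_ln2(self):
        assert float(adversarial_generator_loss(
            Tensor(np.full(4, 0.5, np.float32))).data) \
            == pytest.approx(np.log(2), rel=1e-4)

    def test_generator_loss_decreases_in_realness(self):
        vals = [float(adversarial_generator_loss(
            Tensor(np.full(1, v, np.float32))).data) for v in (0.2, 0.5, 0.9)]
        assert vals[0] > vals[1] > vals[2]

    def test_perfect_discriminator_scores_zero(self):
        loss = discriminator_loss(Tensor(np.ones(3, np.float32)),
                                  Tensor(np.zeros(3, np.float32)))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-5)

    def test_undecided_discriminator_is_two_ln2(self):
        half = Tensor(np.full(3, 0.5, np.float32))
        assert float(discriminator_loss(half, half).data) \
            == pytest.approx(2 * np.log(2), rel=1e-4)


class TestTotal:
    def test_unit_parts_with_baseline_weights(self):
        one = Tensor(np.float32(1.0))
        total, bd = total_student_loss(one, one, one, one, DEFAULT_LAMBDAS)
        assert float(total.data) == pytest.approx(1.75, rel=1e-6)
        assert bd.check_identity()

    def test_zero_weights_reduce_to_supervised(self):
        seg = Tensor(np.float32(0.7))
        part = Tensor(np.float32(5.0))
        total, bd = total_student_loss(seg, part, part, part, (0, 0, 0))
        assert float(total.data) == pytest.approx(0.7)
        assert bd.check_identity()

    def test_ramp_scales_unsupervised_weights(self):
        one = Tensor(np.float32(1.0))
        _, bd = total_student_loss(one, one, one, one, DEFAULT_LAMBDAS,
                                   ramp=0.5)
        assert bd.weights == pytest.approx((0.25, 0.1, 0.025))
        assert bd.check_identity()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_all_losses_nonnegative_and_finite_on_random_inputs(seed):
    rng = np.random.default_rng(seed)
    b, k, n = 2, 3, 4
    p = rng.random((b, k, n, n)).astype(np.float32)
    p /= p.sum(axis=1, keepdims=True)
    q = rng.random((b, k, n, n)).astype(np.float32)
    q /= q.sum(axis=1, keepdims=True)
    y = rng.integers(0, k, (b, n, n))
    d = rng.uniform(0.01, 0.99, b).astype(np.float32)
    eps = consistency_error(Tensor(p), Tensor(q))
    values = [dice_loss(Tensor(p), y), cross_entropy_loss(Tensor(p), y),
              supervised_loss(Tensor(p), y), consistency_loss(eps),
              stabilization_loss(eps.data, eps.data.copy(),
                                 Tensor(eps.data.copy()),
                                 rng.integers(0, 2, b), rng.integers(0, 2, b)),
              adversarial_generator_loss(Tensor(d)),
              discriminator_loss(Tensor(d), Tensor(d))]
    for v in values:
        x = float(v.data)
        assert np.isfinite(x) and x >= 0.0


@pytest.mark.parametrize("loss_builder", [
    lambda p, y: dice_loss(p, y),
    lambda p, y: cross_entropy_loss(p, y),
    lambda p, y: supervised_loss(p, y),
], ids=["dice", "cross_entropy", "supervised"])
def test_loss_gradients_match_finite_differences(monkeypatch, loss_builder):
    """Autograd loss gradients w.r.t. probabilities agree with central
    differences on a 2x2 instance."""
    monkeypatch.setattr(ad, "DEFAULT_DTYPE", np.float64)
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.9, (1, 2, 2, 2))
    y = rng.integers(0, 2, (1, 2, 2))
    t = Tensor(p.copy(), requires_grad=True)
    loss_builder(t, y).backward()
    h = 1e-6
    num = np.zeros_like(p)
    for idx in np.ndindex(p.shape):
        pp, pm = p.copy(), p.copy()
        pp[idx] += h
        pm[idx] -= h
        num[idx] = (float(loss_builder(Tensor(pp), y).data)
                    - float(loss_builder(Tensor(pm), y).data)) / (2 * h)
    np.testing.assert_allclose(t.grad, num, rtol=1e-3, atol=1e-6)
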