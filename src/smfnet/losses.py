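"""Training objectives: supervised (cross-entropy + Dice), consistency,
dual-student stabilization, adversarial, and their weighted totals.

All losses are pure functions of probability tensors; the soft Dice uses
probabilities (argmax Dice lives in the metrics module).  The supervised
objective is (CE + Dice loss)/2; summing the Dice *similarity* into a loss
is contradictory, but that literal reading is available behind
`eq15_dice_as_similarity` for comparison.  The real/fake discriminator
targets use binary cross-entropy on a scalar realness score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

EPS_PROB = 1e-7
DICE_SMOOTH = 1e-6

#: baseline weighting (lambda1, lambda2, lambda3) for the dual-student total
DEFAULT_LAMBDAS = (0.5, 0.2, 0.05)


@dataclass
class LossBreakdown:
    """Components of one student's total objective."""

    seg: float
    cons: float
    sta: float
    adv: float
    total: float
    weights: tuple[float, float, float]

    def check_identity(self, tol: float = 1e-6) -> bool:
        l1, l2, l3 = self.weights
        expect = self.seg + l1 * self.cons + l2 * self.sta + l3 * self.adv
        return abs(self.total - expect) <= tol * max(1.0, abs(expect))


def _one_hot(target: np.ndarray, k: int, dtype) -> np.ndarray:
    oh = np.zeros((target.shape[0], k) + target.shape[1:], dtype=dtype)
    for c in range(k):
        oh[:, c] = target == c
    return oh


def dice_loss(probs: Tensor, target: np.ndarray) -> Tensor:
    """Soft Dice loss: 1 - mean over batch and classes of 2|p.y|/(|p|+|y|)."""
    if probs.shape[0] == 0:
        raise ValueError("empty batch")
    k = probs.shape[1]
    oh = Tensor(_one_hot(target, k, probs.data.dtype))
    inter = (probs * oh).sum(axis=(2, 3))
    sizes = probs.sum(axis=(2, 3)) + oh.sum(axis=(2, 3))
    dice = (inter * 2.0 + DICE_SMOOTH) / (sizes + DICE_SMOOTH)
    return 1.0 - dice.mean()


def cross_entropy_loss(probs: Tensor, target: np.ndarray) -> Tensor:
    """Mean over pixels of -log p(true class), probabilities clipped."""
    k = probs.shape[1]
    oh = Tensor(_one_hot(target, k, probs.data.dtype))
    p_true = (probs.clip(EPS_PROB, 1.0) * oh).sum(axis=1)
    return -(p_true.log().mean())


def supervised_loss(probs: Tensor, target: np.ndarray,
                    eq15_dice_as_similarity: bool = False) -> Tensor:
    """(CE + Dice loss) / 2; the flag swaps in the literal Dice similarity."""
    d = dice_loss(probs, target)
    if eq15_dice_as_similarity:
        d = 1.0 - d
    return (cross_entropy_loss(probs, target) + d) * 0.5


def consistency_error(pred_transform_in: Tensor, transform_pred: Tensor) -> Tensor:
    """Per-pixel squared difference of two probability maps, summed over
    classes: epsilon(x)(i,j) = sum_c (S(T(x)) - T(S(x)))^2."""
    if pred_transform_in.shape != transform_pred.shape:
        raise ValueError(f"shape mismatch: {pred_transform_in.shape} "
                         f"vs {transform_pred.shape}")
    return ((pred_transform_in - transform_pred) ** 2.0).sum(axis=1)


def consistency_loss(epsilon: Tensor) -> Tensor:
    """Spatial (and batch) mean of the consistency error map."""
    return epsilon.mean()


def stabilization_loss(eps_a: np.ndarray, eps_b: np.ndarray, mse_map: Tensor,
                       r_a: np.ndarray, r_b: np.ndarray,
                       flip_indicator: bool = False) -> Tensor:
    """Stability-gated cross-student constraint for student A.

    Per pixel: if r_a = r_b = 1, contribute mse where [eps_a < eps_b] holds
    (the printed indicator direction; `flip_indicator` reverses it);
    otherwise contribute r_a * mse.  Result is the mean over pixels.
    The epsilon maps and flags act as constants; gradients flow only
    through `mse_map`.
    """
    both = (r_a == 1) & (r_b == 1)                       # (B,)
    ind = eps_a > eps_b if flip_indicator else eps_a < eps_b
    gate = np.where(both[:, None, None], ind,
                    r_a[:, None, None].astype(bool))
    return (mse_map * Tensor(gate.astype(mse_map.data.dtype))).mean()


def adversarial_generator_loss(d_out: Tensor) -> Tensor:
    """Cross-entropy of the discriminator score against target 'real' (1)."""
    return -(d_out.clip(EPS_PROB, 1.0).log().mean())


def discriminator_loss(real_out: Tensor, fake_out: Tensor) -> Tensor:
    """CE(real, 1) + CE(fake, 0)."""
    lr = -(real_out.clip(EPS_PROB, 1.0).log().mean())
    lf = -((1.0 - fake_out).clip(EPS_PROB, 1.0).log().mean())
    return lr + lf


def total_student_loss(seg: Tensor, cons: Tensor | None, sta: Tensor | None,
                       adv: Tensor | None,
                       weights: tuple[float, float, float] = DEFAULT_LAMBDAS,
                       ramp: float = 1.0) -> tuple[Tensor, LossBreakdown]:
    """Weighted total per the dual-student objective, with the unsupervised
    weights scaled by the ramp factor.  Returns the differentiable total and
    a float breakdown whose stored weights are the effective (ramped) ones."""
    l1, l2, l3 = (ramp * w for w in weights)
    total = seg
    if cons is not None and l1 > 0:
        total = total + l1 * cons
    if sta is not None and l2 > 0:
        total = total + l2 * sta
    if adv is not None and l3 > 0:
        total = total + l3 * adv
    bd = LossBreakdown(
        seg=float(seg.data),
        cons=float(cons.data) if cons is not None else 0.0,
        sta=float(sta.data) if sta is not None else 0.0,
        adv=float(adv.data) if adv is not None else 0.0,
        total=float(total.data),
        weights=(l1 if cons is not None else 0.0,
                 l2 if sta is not None else 0.0,
                 l3 if adv is not None else 0.0))
    return total, bd
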