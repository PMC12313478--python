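"""DAS-Net training: two independently initialized students exchanging
stability-gated constraints, per-student adversarial discriminators, an
optional EMA teacher, and a Gaussian ramp-up of the unsupervised weight.

Frameworks:

* ``supervised`` — one student, segmentation loss only.
* ``mean_teacher`` — one student with an EMA teacher; the total objective is
  L_s + lambda (L_semi + L_adv1 + L_adv2) with a single ramped lambda.
* ``dual_student`` (default) — students A and B each optimize
  L_seg + l1 L_cons + l2 L_sta + l3 L_adv with baseline weights
  (0.5, 0.2, 0.05); the unsupervised weights are additionally scaled by the
  Gaussian ramp delta*exp(-5 (1-I)^2).  The cross-student stabilization term
  is gated per sample by stability flags (prediction/transport agreement and
  confidence above tau), and gradients flow only into the student that owns
  the term.  When the teacher is enabled, it tracks student A and provides
  the "real" pairs for D2.

Update order per step: students, then discriminators, then the EMA teacher.
When every unsupervised weight is zero the unlabeled branch is skipped
entirely, so the run reduces bit-for-bit to independent supervised training.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Adam, BatchNorm2d, Tensor, no_grad
from .data_io import (Sample, apply_spatial_to_tensor, apply_transform,
                      random_spatial_transform, to_batch)
from .discriminator import Discriminator
from .losses import (DEFAULT_LAMBDAS, LossBreakdown,
                     adversarial_generator_loss, consistency_error,
                     consistency_loss, dice_loss, discriminator_loss,
                     stabilization_loss, supervised_loss, total_student_loss)
from .metrics import MetricReport, evaluate_sample, mean_reports
from .model import ModelConfig, SMFNet, save_checkpoint
from .text import Vocabulary


# ---------------------------------------------------------------------------
# Schedules and EMA
# ---------------------------------------------------------------------------

@dataclass
class RampSchedule:
    """Gaussian ramp of the unsupervised weight: lambda = delta*e^(-5(1-I)^2)."""

    delta: float = 1.0
    ramp_epochs: int = 50

    def weight(self, epoch: int) -> float:
        return ramp_weight(self, epoch)


def ramp_weight(sched: RampSchedule, epoch: int) -> float:
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    I = 1.0 if sched.ramp_epochs <= 0 else min(epoch / sched.ramp_epochs, 1.0)
    return sched.delta * float(np.exp(-5.0 * (1.0 - I) ** 2))


def ema_update(teacher: SMFNet, student: SMFNet, alpha: float) -> None:
    """theta' <- alpha * theta' + (1 - alpha) * theta, elementwise, for all
    parameters and running statistics."""
    t_state = teacher.state_dict()
    s_state = student.state_dict()
    if set(t_state) != set(s_state):
        raise ValueError("teacher/student parameter sets differ")
    merged = {k: alpha * t_state[k].astype(np.float64)
              + (1.0 - alpha) * s_state[k].astype(np.float64)
              for k in t_state}
    teacher.load_state_dict(merged)


def _bn_stats(model) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(m.running_mean.copy(), m.running_var.copy())
            for m in model.modules() if isinstance(m, BatchNorm2d)]


def _restore_bn_stats(model, saved) -> None:
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    for m, (mean, var) in zip(bns, saved):
        m.running_mean[...] = mean
        m.running_var[...] = var


def stability_flag(probs: np.ndarray, probs_perturbed: np.ndarray,
                   tau: float, agreement: float = 0.9) -> np.ndarray:
    """Per-sample stability: 1 iff argmax maps agree on >= `agreement` of the
    pixels AND the mean max-class probability reaches tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    a = probs.argmax(axis=1)
    b = probs_perturbed.argmax(axis=1)
    agree = (a == b).mean(axis=(1, 2))
    conf = probs.max(axis=1).mean(axis=(1, 2))
    return ((agree >= agreement) & (conf >= tau)).astype(np.int64)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    framework: str = "dual_student"     # dual_student | mean_teacher | supervised
    lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS
    schedule: RampSchedule = field(default_factory=RampSchedule)
    alpha: float = 0.999                # EMA smoothing
    tau: float = 0.6                    # stability confidence threshold
    agreement: float = 0.9
    lr: float = 3e-4
    betas: tuple[float, float] = (0.9, 0.99)
    batch_size: int = 4
    unlabeled_batch_size: int = 4
    epochs: int = 10
    patience: int = 100
    use_teacher: bool = False           # dual_student only; mean_teacher always
    flip_stability_indicator: bool = False
    eq15_dice_as_similarity: bool = False
    ema_noise_sd: float = 0.05          # input perturbation for the teacher pair
    disc_channels: int = 8
    supervised_student: str = "a"       # which init stream a supervised run uses
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["lambdas"] = list(self.lambdas)
        d["betas"] = list(self.betas)
        return d


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------

class Trainer:
    def __init__(self, model_cfg: ModelConfig, train_cfg: TrainConfig,
                 vocab: Vocabulary):
        self.mc, self.tc = model_cfg, train_cfg
        seed = train_cfg.seed
        fw = train_cfg.framework
        if fw not in ("supervised", "mean_teacher", "dual_student"):
            raise ValueError(f"unknown framework {fw!r}")

        if fw == "supervised":
            stream = 1 if train_cfg.supervised_student == "a" else 2
            self.students = [SMFNet(model_cfg, vocab, _rng(seed, stream))]
        elif fw == "mean_teacher":
            self.students = [SMFNet(model_cfg, vocab, _rng(seed, 1))]
        else:
            self.students = [SMFNet(model_cfg, vocab, _rng(seed, 1)),
                             SMFNet(model_cfg, vocab, _rng(seed, 2))]
        self.optimizers = [Adam(s.parameters(), lr=train_cfg.lr,
                                betas=train_cfg.betas) for s in self.students]

        self.teacher: SMFNet | None = None
        if fw == "mean_teacher" or (fw == "dual_student" and train_cfg.use_teacher):
            self.teacher = SMFNet(model_cfg, vocab, _rng(seed, 1))
            self.teacher.load_state_dict(self.students[0].state_dict())
            self.teacher.eval()

        self.discriminators: list[Discriminator] = []
        self.d_optimizers: list[Adam] = []
        if fw in ("mean_teacher", "dual_student"):
            for stream in (3, 4):
                d = Discriminator(model_cfg.num_classes, _rng(seed, stream),
                                  base_channels=train_cfg.disc_channels)
                self.discriminators.append(d)
                self.d_optimizers.append(Adam(d.parameters(), lr=train_cfg.lr,
                                              betas=train_cfg.betas))

        self.rng_data = _rng(seed, 10)
        self.rng_unlab = _rng(seed, 11)
        self.rng_aug = _rng(seed, 12)
        self.rng_noise = _rng(seed, 13)

    # ------------------------------------------------------------------ utils
    def _check_finite(self, value: float, component: str) -> None:
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite loss in component {component!r}")

    def _unsup_active(self, epoch: int) -> bool:
        if self.tc.framework == "supervised":
            return False
        if self.tc.framework == "mean_teacher":
            return True
        ramp = ramp_weight(self.tc.schedule, epoch)
        return any(ramp * w > 0 for w in self.tc.lambdas)

    # ------------------------------------------------------------- train steps
    def train_step(self, labeled: list[Sample], unlabeled: list[Sample],
                   epoch: int) -> dict[str, LossBreakdown]:
        if not labeled:
            raise ValueError("at least one labeled sample per step is required")
        if self.tc.framework == "dual_student":
            return self._step_dual(labeled, unlabeled, epoch)
        if self.tc.framework == "mean_teacher":
            return self._step_mean_teacher(labeled, unlabeled, epoch)
        return {"a": self._step_supervised_single(self.students[0],
                                                  self.optimizers[0], labeled)}

    def _supervised_part(self, student: SMFNet, labeled: list[Sample]):
        img, mask, texts = to_batch(labeled)
        out = student(Tensor(img.pixels), texts)
        seg = supervised_loss(out.probs, mask.labels,
                              self.tc.eq15_dice_as_similarity)
        return out, seg

    def _step_supervised_single(self, student, opt, labeled) -> LossBreakdown:
        opt.zero_grad()
        _, seg = self._supervised_part(student, labeled)
        self._check_finite(float(seg.data), "seg")
        total, bd = total_student_loss(seg, None, None, None, self.tc.lambdas)
        total.backward()
        opt.step()
        return bd

    def _step_dual(self, labeled, unlabeled, epoch):
        tc = self.tc
        unsup = self._unsup_active(epoch) and len(unlabeled) > 0
        if not unsup:
            return {"a": self._step_supervised_single(
                        self.students[0], self.optimizers[0], labeled),
                    "b": self._step_supervised_single(
                        self.students[1], self.optimizers[1], labeled)}

        ramp = ramp_weight(tc.schedule, epoch)
        img_u, _, texts_u = to_batch(unlabeled)
        T = random_spatial_transform(self.rng_aug)
        img_uT, _ = apply_transform(T, img_u)

        # Pre-update predictions of both students on the unlabeled batch,
        # computed without graphs so only one student's graph is ever alive.
        # Train-mode batchnorm depends on batch statistics only, so these
        # equal the graph-building forwards below bit for bit; running stats
        # are restored to avoid counting the batch twice.
        pre: dict[str, dict] = {}
        for name, student in zip("ab", self.students):
            saved = _bn_stats(student)
            with no_grad():
                probs_Tu = student(Tensor(img_uT.pixels), texts_u).probs
                probs_u = student(Tensor(img_u.pixels), texts_u).probs
            _restore_bn_stats(student, saved)
            transported = apply_spatial_to_tensor(T, probs_u)
            eps = consistency_error(probs_Tu, transported)
            r = stability_flag(transported.data, probs_Tu.data,
                               tc.tau, tc.agreement)
            pre[name] = dict(probs_Tu=probs_Tu.data, eps=eps.data, r=r)

        breakdowns: dict[str, LossBreakdown] = {}
        img_l, _, _ = to_batch(labeled)
        pred_for_disc: dict[str, dict] = {}
        for name, other in (("a", "b"), ("b", "a")):
            idx = 0 if name == "a" else 1
            student, opt = self.students[idx], self.optimizers[idx]
            disc = self.discriminators[idx]
            out_l, seg = self._supervised_part(student, labeled)
            out_Tu = student(Tensor(img_uT.pixels), texts_u)
            out_u = student(Tensor(img_u.pixels), texts_u)
            transported = apply_spatial_to_tensor(T, out_u.probs)
            eps = consistency_error(out_Tu.probs, transported)
            cons = consistency_loss(eps)
            mse_map = ((out_Tu.probs
                        - Tensor(pre[other]["probs_Tu"])) ** 2.0).sum(axis=1)
            sta = stabilization_loss(pre[name]["eps"], pre[other]["eps"],
                                     mse_map, pre[name]["r"], pre[other]["r"],
                                     tc.flip_stability_indicator)
            adv = adversarial_generator_loss(disc(Tensor(img_u.pixels),
                                                  out_u.probs))
            for comp, val in (("seg", seg), ("cons", cons),
                              ("sta", sta), ("adv", adv)):
                self._check_finite(float(val.data), comp)
            total, bd = total_student_loss(seg, cons, sta, adv,
                                           tc.lambdas, ramp)
            opt.zero_grad()
            disc.zero_grad()
            total.backward()
            opt.step()
            breakdowns[name] = bd
            pred_for_disc[name] = {"l": out_l.probs.data.copy(),
                                   "u": out_u.probs.data.copy()}
            del out_l, out_Tu, out_u, transported, eps, mse_map, total

        # discriminator updates (Eq. 10/11 pairs), on detached predictions
        for idx, name in enumerate("ab"):
            disc, dopt = self.discriminators[idx], self.d_optimizers[idx]
            fake = disc(Tensor(img_u.pixels), Tensor(pred_for_disc[name]["u"]))
            if idx == 1 and self.teacher is not None:
                noise = self.rng_noise.normal(0.0, tc.ema_noise_sd,
                                              img_u.pixels.shape)
                x_ema = np.clip(img_u.pixels + noise.astype(np.float32), 0, 1)
                t_out = self.teacher.predict(Tensor(x_ema), texts_u)
                real = disc(Tensor(x_ema), t_out.probs)
            else:
                real = disc(Tensor(img_l.pixels),
                            Tensor(pred_for_disc[name]["l"]))
            d_loss = discriminator_loss(real, fake)
            self._check_finite(float(d_loss.data), f"disc_{name}")
            dopt.zero_grad()
            d_loss.backward()
            dopt.step()

        if self.teacher is not None:
            ema_update(self.teacher, self.students[0], tc.alpha)
        return breakdowns

    def _step_mean_teacher(self, labeled, unlabeled, epoch):
        tc = self.tc
        student, opt = self.students[0], self.optimizers[0]
        lam = ramp_weight(tc.schedule, epoch)

        img_l, mask_l, texts_l = to_batch(labeled)
        out_l = student(Tensor(img_l.pixels), texts_l)
        seg = dice_loss(out_l.probs, mask_l.labels)

        semi = adv = None
        out_u = None
        if unlabeled:
            img_u, _, texts_u = to_batch(unlabeled)
            noise = self.rng_noise.normal(0.0, tc.ema_noise_sd,
                                          img_u.pixels.shape)
            x_ema = np.clip(img_u.pixels + noise.astype(np.float32), 0, 1)
            with no_grad():
                t_out = self.teacher.predict(Tensor(x_ema), texts_u)
            out_u = student(Tensor(img_u.pixels), texts_u)
            semi = ((out_u.probs - Tensor(t_out.probs.data)) ** 2.0).mean()
            adv = (adversarial_generator_loss(
                       self.discriminators[0](Tensor(img_u.pixels), out_u.probs))
                   + adversarial_generator_loss(
                       self.discriminators[1](Tensor(img_u.pixels), out_u.probs)))
        total = seg
        if semi is not None:
            total = total + lam * (semi + adv)
        for comp, val in (("seg", seg), ("semi", semi), ("adv", adv)):
            if val is not None:
                self._check_finite(float(val.data), comp)
        opt.zero_grad()
        for d in self.discriminators:
            d.zero_grad()
        total.backward()
        opt.step()

        if unlabeled:
            for idx, (real_pair, fake_probs) in enumerate((
                    ((img_l.pixels, out_l.probs.detach()), out_u.probs.detach()),
                    ((x_ema, t_out.probs), out_u.probs.detach()))):
                disc, dopt = self.discriminators[idx], self.d_optimizers[idx]
                real = disc(Tensor(real_pair[0]), real_pair[1])
                fake = disc(Tensor(img_u.pixels), fake_probs)
                d_loss = discriminator_loss(real, fake)
                dopt.zero_grad()
                d_loss.backward()
                dopt.step()

        ema_update(self.teacher, student, tc.alpha)
        bd = LossBreakdown(seg=float(seg.data),
                           cons=float(semi.data) if semi is not None else 0.0,
                           sta=0.0,
                           adv=float(adv.data) if adv is not None else 0.0,
                           total=float(total.data),
                           weights=(lam if semi is not None else 0.0, 0.0,
                                    lam if adv is not None else 0.0))
        return {"a": bd}

    # ------------------------------------------------------------------- fit
    def fit(self, labeled: list[Sample], unlabeled: list[Sample],
            val: list[Sample], epochs: int | None = None,
            out_dir: Path | None = None) -> dict:
        """Run training with per-epoch validation and early stopping on the
        validation mean Dice; returns the metric history and restores the
        best parameters into student A."""
        if not labeled:
            raise ValueError("fit requires a non-empty labeled set")
        tc = self.tc
        epochs = epochs if epochs is not None else tc.epochs
        history: list[dict] = []
        best_dice, best_state, best_epoch = -np.inf, None, -1
        for epoch in range(epochs):
            order = self.rng_data.permutation(len(labeled))
            losses: list[LossBreakdown] = []
            for start in range(0, len(labeled), tc.batch_size):
                batch = [labeled[i] for i in order[start:start + tc.batch_size]]
                ubatch: list[Sample] = []
                if unlabeled and self._unsup_active(epoch):
                    uidx = self.rng_unlab.choice(
                        len(unlabeled),
                        size=min(tc.unlabeled_batch_size, len(unlabeled)),
                        replace=False)
                    ubatch = [unlabeled[i] for i in uidx]
                bds = self.train_step(batch, ubatch, epoch)
                losses.extend(bds.values())
            record = {"epoch": epoch,
                      "loss": {k: float(np.mean([getattr(b, k) for b in losses]))
                               for k in ("seg", "cons", "sta", "adv", "total")}}
            if val:
                # model selection: with two students, keep whichever
                # validates better
                reports = [evaluate_model(s, val) for s in self.students]
                record["val"] = reports[0].to_dict()
                if len(reports) > 1:
                    record["val_student_b"] = reports[1].to_dict()
                for student, report in zip(self.students, reports):
                    dice = report.mean_dice
                    if np.isfinite(dice) and dice > best_dice:
                        best_dice, best_epoch = dice, epoch
                        best_state = copy.deepcopy(student.state_dict())
                if epoch - best_epoch >= tc.patience:
                    history.append(record)
                    break
            history.append(record)
        if best_state is not None:
            self.students[0].load_state_dict(best_state)
        result = {"history": history, "best_val_dice": float(best_dice),
                  "best_epoch": int(best_epoch),
                  "config": {"model": asdict(self.mc),
                             "train": tc.to_jsonable()}}
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(out_dir / "checkpoint.npz", self.students[0])
            (out_dir / "history.json").write_text(json.dumps(result, indent=1))
        return result


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def evaluate_model(model: SMFNet, samples: list[Sample],
                   batch_size: int = 8) -> MetricReport:
    """Mean per-sample metric report over a labeled sample list."""
    reports = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        img, mask, texts = to_batch(chunk)
        out = model.predict(Tensor(img.pixels), texts)
        probs = out.probs.data
        labels = probs.argmax(axis=1)
        for i in range(len(chunk)):
            reports.append(evaluate_sample(labels[i], mask.labels[i], probs[i]))
    return mean_reports(reports)
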