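"""Training machinery: EMA, ramp-up, stability flags, dual-student steps,
supervised reduction, and the fit loop."""

import numpy as np
import pytest

from smfnet.data_io import Sample
from smfnet.model import nano_config
from smfnet.synthetic import generate_samples, tiny_spec
from smfnet.text import Vocabulary
from smfnet.trainer import (RampSchedule, TrainConfig, Trainer, ema_update,
                            ramp_weight, stability_flag)

ALPHA = 0.999


class TestEMA:
    def _pair(self, vocab):
        from smfnet.model import SMFNet
        t = SMFNet(nano_config(), vocab, np.random.default_rng(1))
        s = SMFNet(nano_config(), vocab, np.random.default_rng(2))
        return t, s

    def test_single_update_closed_form(self, vocab):
        t, s = self._pair(vocab)
        for p in t.parameters():
            p.data[...] = 0.0
        for p in s.parameters():
            p.data[...] = 1.0
        ema_update(t, s, ALPHA)
        for p in t.parameters():
            np.testing.assert_allclose(p.data, 0.001, rtol=1e-4)

    def test_equal_parameters_are_a_fixed_point(self, vocab):
        t, s = self._pair(vocab)
        t.load_state_dict(s.state_dict())
        before = {k: v.copy() for k, v in t.state_dict().items()}
        ema_update(t, s, ALPHA)
        for k, v in t.state_dict().items():
            np.testing.assert_allclose(v, before[k], rtol=1e-6)

    def test_constant_student_geometric_recursion(self, vocab):
        """After n updates toward a constant student:
        theta'_n = alpha^n theta'_0 + (1 - alpha^n) theta."""
        t, s = self._pair(vocab)
        theta0 = {k: v.copy() for k, v in t.state_dict().items()}
        n = 7
        for _ in range(n):
            ema_update(t, s, ALPHA)
        sstate = s.state_dict()
        for k, v in t.state_dict().items():
            expect = ALPHA ** n * theta0[k] + (1 - ALPHA ** n) * sstate[k]
            np.testing.assert_allclose(v, expect, rtol=1e-4, atol=1e-7)

    def test_teacher_stays_in_student_convex_hull(self, vocab):
        t, s = self._pair(vocab)
        lo = {k: np.minimum(a, b) for (k, a), b in
              zip(t.state_dict().items(), s.state_dict().values())}
        hi = {k: np.maximum(a, b) for (k, a), b in
              zip(t.state_dict().items(), s.state_dict().values())}
        for _ in range(5):
            ema_update(t, s, 0.9)
        for k, v in t.state_dict().items():
            assert (v >= lo[k] - 1e-6).all() and (v <= hi[k] + 1e-6).all()


class TestRamp:
    def test_plateau_at_delta_after_ramp(self):
        sched = RampSchedule(delta=2.0, ramp_epochs=10)
        assert ramp_weight(sched, 10) == pytest.approx(2.0)
        assert ramp_weight(sched, 25) == pytest.approx(2.0)

    def test_start_value_is_delta_times_exp_minus_five(self):
        sched = RampSchedule(delta=1.0, ramp_epochs=50)
        assert ramp_weight(sched, 0) == pytest.approx(np.exp(-5.0), rel=1e-6)

    def test_strictly_increasing_over_the_ramp(self):
        sched = RampSchedule(delta=1.0, ramp_epochs=20)
        vals = [ramp_weight(sched, e) for e in range(21)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[0] < vals[10] < vals[20] == 1.0

    def test_zero_ramp_epochs_means_full_weight(self):
        assert ramp_weight(RampSchedule(1.0, 0), 0) == pytest.approx(1.0)


class TestStabilityFlag:
    def test_identical_confident_predictions_are_stable(self):
        p = np.zeros((1, 3, 4, 4))
        p[:, 1] = 0.99
        p[:, 0] = p[:, 2] = 0.005
        assert stability_flag(p, p.copy(), tau=0.6)[0] == 1

    def test_uniform_predictions_fail_confidence(self):
        p = np.full((1, 3, 4, 4), 1 / 3)
        assert stability_flag(p, p.copy(), tau=0.6)[0] == 0

    def test_agreement_fraction_matches_pixel_count(self):
        """Brute-force count on a 4x4 toy with a controlled disagreement."""
        a = np.zeros((1, 2, 4, 4))
        a[:, 1] = 0.9
        a[:, 0] = 0.1
        b = a.copy()
        b[0, :, 0, 0] = [0.9, 0.1]  # one disagreeing pixel -> 15/16 agreement
        manual = (a.argmax(1) == b.argmax(1)).mean()
        assert manual == pytest.approx(15 / 16)
        assert stability_flag(a, b, tau=0.6, agreement=0.9)[0] == 1
        assert stability_flag(a, b, tau=0.6, agreement=0.97)[0] == 0

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            stability_flag(np.zeros((1, 2, 2, 2)), np.zeros((1, 2, 2, 2)),
                           tau=1.5)


@pytest.fixture(scope="module")
def tiny_data():
    pool = generate_samples(8, tiny_spec(), seed=21)
    labeled = pool[:4]
    unlabeled = [Sample(s.id, s.image, s.text) for s in pool[4:]]
    vocab = Vocabulary.build([s.text for s in pool])
    return labeled, unlabeled, vocab


class TestDualStudentStep:
    def test_losses_finite_nonnegative_and_identity_holds(self, tiny_data):
        labeled, unlabeled, vocab = tiny_data
        tc = TrainConfig(framework="dual_student",
                         schedule=RampSchedule(ramp_epochs=2),
                         batch_size=2, unlabeled_batch_size=2, seed=3)
        tr = Trainer(nano_config(), tc, vocab)
        for step in range(2):
            bds = tr.train_step(labeled[:2], unlabeled[:2], epoch=step)
            assert set(bds) == {"a", "b"}
            for bd in bds.values():
                for part in (bd.seg, bd.cons, bd.sta, bd.adv):
                    assert np.isfinite(part) and part >= 0
                assert bd.check_identity(tol=1e-5)

    def test_requires_labeled_samples(self, tiny_data):
        _, unlabeled, vocab = tiny_data
        tr = Trainer(nano_config(), TrainConfig(seed=0), vocab)
        with pytest.raises(ValueError, match="labeled"):
            tr.train_step([], unlabeled[:2], epoch=0)

    def test_zero_weights_reduce_to_independent_supervised_runs(self,
                                                                tiny_data):
        """With all unsupervised weights zero, 5 dual-student steps produce
        parameter trajectories bit-identical to two independent supervised
        runs with the matching initialization streams."""
        labeled, unlabeled, vocab = tiny_data
        seed = 11
        dual = Trainer(nano_config(), TrainConfig(
            framework="dual_student", lambdas=(0.0, 0.0, 0.0), seed=seed,
            batch_size=2), vocab)
        sups = [Trainer(nano_config(), TrainConfig(
            framework="supervised", seed=seed, batch_size=2,
            supervised_student=which), vocab) for which in ("a", "b")]
        for step in range(5):
            batch = labeled[step % 2: step % 2 + 2]
            dual.train_step(batch, unlabeled[:2], epoch=step)
            for sup in sups:
                sup.train_step(batch, [], epoch=step)
        for student, sup in zip(dual.students, sups):
            ds, ss = student.state_dict(), sup.students[0].state_dict()
            for k in ds:
                np.testing.assert_array_equal(ds[k], ss[k], err_msg=k)


class TestMeanTeacherStep:
    def test_step_runs_and_teacher_moves_toward_student(self, tiny_data):
        labeled, unlabeled, vocab = tiny_data
        tc = TrainConfig(framework="mean_teacher", alpha=0.9,
                         schedule=RampSchedule(ramp_epochs=2),
                         batch_size=2, seed=5)
        tr = Trainer(nano_config(), tc, vocab)
        t0 = {k: v.copy() for k, v in tr.teacher.state_dict().items()}
        bd = tr.train_step(labeled[:2], unlabeled[:2], epoch=0)["a"]
        assert np.isfinite(bd.total)
        s = tr.students[0].state_dict()
        moved = any(not np.array_equal(v, t0[k])
                    for k, v in tr.teacher.state_dict().items())
        assert moved
        # convexity: teacher between old teacher and current student
        for k, v in tr.teacher.state_dict().items():
            lo = np.minimum(t0[k], s[k]) - 1e-6
            hi = np.maximum(t0[k], s[k]) + 1e-6
            assert ((v >= lo) & (v <= hi)).all()


class TestFit:
    def test_smoke_run_writes_checkpoint_and_history(self, tiny_data,
                                                     tmp_path):
        labeled, unlabeled, vocab = tiny_data
        tc = TrainConfig(framework="supervised", epochs=3, batch_size=4,
                         lr=1e-3, seed=9)
        tr = Trainer(nano_config(), tc, vocab)
        result = tr.fit(labeled, [], labeled, out_dir=tmp_path)
        assert (tmp_path / "checkpoint.npz").exists()
        assert (tmp_path / "history.json").exists()
        assert len(result["history"]) == 3
        seg = [h["loss"]["seg"] for h in result["history"]]
        assert seg[2] < seg[0]          # monitored descent on the overfit set
        assert np.isfinite(result["best_val_dice"])

    def test_same_seed_reproduces_identical_history(self, tiny_data):
        labeled, _, vocab = tiny_data
        def run():
            tc = TrainConfig(framework="supervised", epochs=2, batch_size=2,
                             seed=13)
            return Trainer(nano_config(), tc, vocab).fit(labeled, [], labeled)
        assert run()["history"] == run()["history"]

    def test_empty_labeled_set_rejected(self, tiny_data):
        _, _, vocab = tiny_data
        tr = Trainer(nano_config(), TrainConfig(seed=0), vocab)
        with pytest.raises(ValueError, match="labeled"):
            tr.fit([], [], [])
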