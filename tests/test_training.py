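"""One-cycle schedule, LR range test, training loop and fine-tuning."""

import numpy as np
import pytest

from ppgsleep import (
    LRSchedule,
    RangeTestError,
    SleepStager,
    fine_tune,
    lr_range_test,
    one_cycle_lr,
    train,
)
from ppgsleep.training import model_step_fn

from conftest import toy_windows


class TestOneCycleSchedule:
    SCHED = LRSchedule(1e-4, 1e-3, ramp_epochs=5)

    def test_peak_at_end_of_ramp(self):
        assert one_cycle_lr(5, self.SCHED) == pytest.approx(1e-3)

    def test_starts_and_returns_to_minimum(self):
        assert one_cycle_lr(0, self.SCHED) == pytest.approx(1e-4)
        assert one_cycle_lr(10, self.SCHED) == pytest.approx(1e-4)

    def test_final_rate_two_decades_below_minimum(self):
        assert one_cycle_lr(30, self.SCHED) == pytest.approx(1e-6)

    def test_tail_geometric_interpolation(self):
        # tail epoch k=10 of 20: 1e-4 * 10^-1
        assert one_cycle_lr(20, self.SCHED) == pytest.approx(1e-5)

    def test_boundary_continuity(self):
        r = self.SCHED.ramp_epochs
        up_end = one_cycle_lr(r, self.SCHED)
        down_start = one_cycle_lr(r, self.SCHED)
        assert up_end == down_start
        assert one_cycle_lr(2 * r, self.SCHED) == pytest.approx(
            self.SCHED.lr_min)

    def test_linear_ramps(self):
        assert one_cycle_lr(1, self.SCHED) == pytest.approx(
            1e-4 + (1e-3 - 1e-4) / 5)
        assert one_cycle_lr(7, self.SCHED) == pytest.approx(
            1e-3 - 2 * (1e-3 - 1e-4) / 5)

    def test_index_beyond_end_rejected(self):
        with pytest.raises(IndexError):
            one_cycle_lr(31, self.SCHED)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            LRSchedule(1e-3, 1e-4, ramp_epochs=5)


class TestLRRangeTest:
    def test_quadratic_surrogate_bracketed(self):
        # analytic surrogate: one gradient step on f(w) = a w^2 / 2 from w0
        # leaves loss a*(w0*(1-a*lr))^2/2 -> minimum at lr = 1/a,
        # divergence beyond 2/a
        a = 100.0
        w0 = 1.0

        def step(lr):
            w = w0 * (1 - a * lr)
            return 0.5 * a * w * w

        res = lr_range_test(step, 1e-5, 1.0, steps=60)
        assert 1e-4 < res.lr_max < 2.0 / a
        assert res.lr_min == pytest.approx(res.lr_max / 10)

    def test_curve_length_equals_steps(self):
        res = lr_range_test(lambda lr: 1.0 / (1 + lr), 1e-4, 1e-1, steps=37)
        assert len(res.lrs) == len(res.losses) == 37

    def test_monotone_increasing_loss_is_an_error(self):
        with pytest.raises(RangeTestError):
            lr_range_test(lambda lr: 1.0 + lr, 1e-4, 1e-1, steps=30)

    def test_model_backed_step(self, tiny_spec):
        model = SleepStager(tiny_spec, n_classes=3, seed=0)
        w, y = toy_windows(tiny_spec, 24, 3, seed=1)
        nights = [(w[:12], y[:12]), (w[12:], y[12:])]
        res = lr_range_test(model_step_fn(model, nights), 1e-4, 3.0, steps=40)
        assert 0 < res.lr_min < res.lr_max


class TestTrain:
    def _nights(self, tiny_spec, n_nights, per_night, seed=0):
        nights = []
        for i in range(n_nights):
            w, y = toy_windows(tiny_spec, per_night, 3, seed=seed + i)
            nights.append((w, y))
        return nights

    def test_separable_toy_reaches_low_loss(self, tiny_spec):
        model = SleepStager(tiny_spec, n_classes=3, seed=2)
        nights = self._nights(tiny_spec, 4, 24)
        sched = LRSchedule(1e-2, 1e-1, ramp_epochs=8, tail_epochs=4)
        hist = train(model, nights[:3], nights[3:], sched, seed=0)
        assert hist.frame["train_loss"].iloc[-1] < 0.15

    def test_history_and_model_selection(self, tiny_spec):
        model = SleepStager(tiny_spec, n_classes=3, seed=2)
        nights = self._nights(tiny_spec, 3, 12)
        sched = LRSchedule(1e-3, 1e-2, ramp_epochs=2, tail_epochs=2)
        hist = train(model, nights[:2], nights[2:], sched, seed=0)
        frame = hist.frame
        assert list(frame.columns) == ["epoch", "lr", "train_loss", "val_loss"]
        assert len(frame) == sched.n_epochs
        # returned weights are those of the validation-loss argmin
        assert hist.best_epoch == int(frame["val_loss"].idxmin())

    def test_seeded_reproducibility(self, tiny_spec):
        nights = self._nights(tiny_spec, 3, 10)
        sched = LRSchedule(1e-3, 1e-2, ramp_epochs=2, tail_epochs=2)
        hists = []
        for _ in range(2):
            model = SleepStager(tiny_spec, n_classes=3, seed=5)
            hists.append(train(model, nights[:2], nights[2:], sched, seed=7))
        assert np.allclose(hists[0].frame["train_loss"],
                           hists[1].frame["train_loss"], atol=0)

    def test_empty_sets_rejected(self, tiny_spec):
        model = SleepStager(tiny_spec, n_classes=3)
        sched = LRSchedule(1e-3, 1e-2, ramp_epochs=2)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, [], [], sched)


class TestFineTune:
    def test_lr_scaling(self):
        sched = LRSchedule(1e-4, 1e-3, ramp_epochs=5)
        scaled = sched.scaled(0.1)
        assert scaled.lr_min == pytest.approx(1e-5)
        assert scaled.lr_max == pytest.approx(1e-4)

    def test_zero_rate_limit_keeps_weights(self, tiny_spec):
        pre = SleepStager(tiny_spec, n_classes=3, seed=3)
        w, y = toy_windows(tiny_spec, 10, 3)
        sched = LRSchedule(1e-3, 1e-2, ramp_epochs=1, tail_epochs=1)
        before = [p.value.copy() for p in pre.parameters()]
        model, _ = fine_tune(pre, [(w, y)], [(w, y)], sched, lr_scale=1e-14,
                             seed=0, n_epochs=2)
        after = [p.value for p in model.parameters()]
        assert all(np.allclose(a, b, atol=1e-9)
                   for a, b in zip(before, after))

    def test_class_mismatch_reinitializes_head(self, tiny_spec):
        pre = SleepStager(tiny_spec, n_classes=5, seed=3)
        w, y = toy_windows(tiny_spec, 10, 3)
        sched = LRSchedule(1e-3, 1e-2, ramp_epochs=1, tail_epochs=1)
        with pytest.warns(UserWarning, match="mismatch"):
            model, _ = fine_tune(pre, [(w, y)], [(w, y)], sched,
                                 lr_scale=1e-14, seed=0, n_classes=3,
                                 n_epochs=1)
        assert model.n_classes == 3

    def test_pretraining_transfers_across_physiologies(self, tiny_spec):
        # paired comparison: fine-tuning a model pretrained on domain A
        # reaches val loss on domain B no worse than training from scratch
        # at the same (small) budget, averaged over seeds
        pre_sched = LRSchedule(1e-2, 1e-1, ramp_epochs=8, tail_epochs=4)
        sched = LRSchedule(2e-3, 2e-2, ramp_epochs=2, tail_epochs=2)
        gains = []
        for seed in range(3):
            a_nights = [toy_windows(tiny_spec, 16, 3, seed=10 + seed + i,
                                    separation=3.0) for i in range(3)]
            b_nights = [toy_windows(tiny_spec, 16, 3, seed=40 + seed + i,
                                    separation=2.5) for i in range(3)]
            pre = SleepStager(tiny_spec, n_classes=3, seed=seed)
            train(pre, a_nights[:2], a_nights[2:], pre_sched, seed=seed)
            _, hist_ft = fine_tune(pre, b_nights[:2], b_nights[2:], sched,
                                   lr_scale=0.2, seed=seed, n_epochs=2)
            scratch = SleepStager(tiny_spec, n_classes=3, seed=seed + 100)
            hist_sc = train(scratch, b_nights[:2], b_nights[2:], sched,
                            seed=seed, n_epochs=2)
            gains.append(hist_sc.frame["val_loss"].min()
                         - hist_ft.frame["val_loss"].min())
        assert np.mean(gains) >= 0
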