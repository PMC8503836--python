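"""Training the stager: one-cycle schedule, LR range test, fine-tuning.

The learning rate follows a one-cycle policy over *training epochs*: linear
ramp from ``lr_min`` to ``lr_max``, a symmetric linear ramp back down, then
an exponential tail that ends two orders of magnitude below ``lr_min``.  A
learning-rate range test (exponentially spaced one-step probes) suggests the
cycle's bounds.  Optimization is plain momentum SGD, one full night per
step; training always uses non-overlapping 30-s epochs — overlap is an
inference-time device only.  The weights returned are those of the epoch
with the lowest validation cross-entropy.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.stager import SleepStager

__all__ = [
    "LRSchedule",
    "one_cycle_lr",
    "RangeTestError",
    "LRRangeResult",
    "lr_range_test",
    "TrainingHistory",
    "train",
    "fine_tune",
    "SGD",
]


@dataclass(frozen=True)
class LRSchedule:
    """One-cycle schedule: up ``ramp`` epochs, down ``ramp``, exponential tail."""

    lr_min: float
    lr_max: float
    ramp_epochs: int
    tail_epochs: int = 20
    tail_floor: float | None = None  # defaults to lr_min / 100

    def __post_init__(self):
        if not 0 < self.lr_min < self.lr_max:
            raise ValueError("need 0 < lr_min < lr_max")
        if self.ramp_epochs < 1 or self.tail_epochs < 1:
            raise ValueError("ramp and tail must be at least one epoch")

    @property
    def floor(self) -> float:
        return self.tail_floor if self.tail_floor is not None else self.lr_min / 100.0

    @property
    def n_epochs(self) -> int:
        """Number of valid epoch indices (0 .. 2*ramp + tail inclusive)."""
        return 2 * self.ramp_epochs + self.tail_epochs + 1

    def scaled(self, factor: float) -> "LRSchedule":
        return LRSchedule(self.lr_min * factor, self.lr_max * factor,
                          self.ramp_epochs, self.tail_epochs,
                          self.floor * factor)


def one_cycle_lr(epoch_index: int, sched: LRSchedule) -> float:
    """Learning rate at a given training-epoch index.

    lr(0) = lr_min, lr(ramp) = lr_max, lr(2*ramp) = lr_min, then for
    k = 1..tail: lr = lr_min * (floor/lr_min)^(k/tail).
    """
    if epoch_index < 0:
        raise IndexError("epoch index must be non-negative")
    r = sched.ramp_epochs
    if epoch_index <= r:
        frac = epoch_index / r
        return sched.lr_min + frac * (sched.lr_max - sched.lr_min)
    if epoch_index <= 2 * r:
        frac = (epoch_index - r) / r
        return sched.lr_max - frac * (sched.lr_max - sched.lr_min)
    k = epoch_index - 2 * r
    if k > sched.tail_epochs:
        raise IndexError(
            f"epoch {epoch_index} beyond schedule end ({sched.n_epochs - 1})")
    return sched.lr_min * (sched.floor / sched.lr_min) ** (k / sched.tail_epochs)


class RangeTestError(RuntimeError):
    """The loss never descended over the swept learning-rate range."""


@dataclass
class LRRangeResult:
    lrs: np.ndarray
    losses: np.ndarray
    smoothed: np.ndarray
    lr_min: float
    lr_max: float


def lr_range_test(step_fn, lr_lo: float, lr_hi: float, steps: int = 50,
                  smooth: int = 5) -> LRRangeResult:
    """Sweep exponentially spaced learning rates and suggest a cycle range.

    ``step_fn(lr) -> loss`` performs one optimization step at the given rate
    on the next batch (a model-backed step for real training, or any loss
    surrogate).  The suggested ``lr_max`` sits at the steepest descent of the
    smoothed curve before its minimum, with ``lr_min = lr_max / 10``.

    Raises :class:`RangeTestError` when the smoothed loss only increases.
    """
    if not 0 < lr_lo < lr_hi:
        raise ValueError("need 0 < lr_lo < lr_hi")
    if steps < max(3, smooth):
        raise ValueError("too few steps for a range test")
    lrs = np.geomspace(lr_lo, lr_hi, steps)
    losses = np.empty(steps)
    for i, lr in enumerate(lrs):
        losses[i] = float(step_fn(float(lr)))
        if not np.isfinite(losses[i]):
            losses[i:] = losses[max(i - 1, 0)] if i else np.inf
            lrs, losses = lrs[: i + 1], losses[: i + 1]
            break
    kernel = np.ones(min(smooth, len(losses))) / min(smooth, len(losses))
    smoothed = np.convolve(losses, kernel, mode="valid")
    i_min = int(np.argmin(smoothed))
    if i_min == 0 or smoothed[i_min] >= smoothed[0] - 1e-12:
        raise RangeTestError("loss never descended over the swept range")
    log_lr = np.log(lrs[: len(smoothed)])
    slopes = np.diff(smoothed) / np.diff(log_lr)
    i_steep = int(np.argmin(slopes[:i_min])) if i_min >= 1 else 0
    lr_max = float(lrs[i_steep + 1])
    return LRRangeResult(lrs, losses, smoothed, lr_max / 10.0, lr_max)


class SGD:
    """Momentum SGD over a parameter list."""

    def __init__(self, params, momentum: float = 0.9):
        self.params = list(params)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float):
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= lr * p.grad
            p.value += v
            p.grad[:] = 0.0


@dataclass
class TrainingHistory:
    frame: pd.DataFrame  # epoch, lr, train_loss, val_loss
    best_epoch: int

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


def _validation_loss(model: SleepStager, nights) -> float:
    total, count = 0.0, 0
    for windows, labels in nights:
        probs = model.forward(windows)
        eps = 1e-12
        total += -np.log(probs[np.arange(len(labels)), labels] + eps).sum()
        count += len(labels)
    return total / count


def _snapshot(model: SleepStager):
    params = [p.value.copy() for p in model.parameters()]
    bufs = [b.copy() for c in model.components().values() for b in c.buffers()]
    return params, bufs


def _restore(model: SleepStager, snap):
    params, bufs = snap
    for p, v in zip(model.parameters(), params):
        p.value[...] = v
    for b, v in zip(
        [b for c in model.components().values() for b in c.buffers()], bufs):
        b[...] = v


def train(model: SleepStager, train_nights, val_nights, sched: LRSchedule,
          seed: int = 0, momentum: float = 0.9, lr_scale: float = 1.0,
          n_epochs: int | None = None) -> TrainingHistory:
    """Fit the stager with one-cycle momentum SGD, one night per step.

    ``train_nights``/``val_nights`` are lists of ``(windows, labels)`` pairs
    for disjoint patients (split by patient, never by epoch).  The model is
    left holding the weights of the epoch with minimum validation loss.
    ``n_epochs`` may truncate the schedule for short experiments.
    """
    if not train_nights or not val_nights:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), momentum=momentum)
    total = sched.n_epochs if n_epochs is None else min(n_epochs, sched.n_epochs)
    rows = []
    best = (np.inf, -1, None)
    for epoch in range(total):
        lr = one_cycle_lr(epoch, sched) * lr_scale
        order = rng.permutation(len(train_nights))
        losses = []
        for i in order:
            windows, labels = train_nights[i]
            loss = model.loss_and_gradients(windows, labels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, night {i} "
                    f"(lr={lr:.3g}); aborting")
            opt.step(lr)
            losses.append(loss)
        val = _validation_loss(model, val_nights)
        rows.append({"epoch": epoch, "lr": lr,
                     "train_loss": float(np.mean(losses)), "val_loss": val})
        if val < best[0]:
            best = (val, epoch, _snapshot(model))
    if best[2] is not None:
        _restore(model, best[2])
    return TrainingHistory(pd.DataFrame(rows), best_epoch=best[1])


def fine_tune(pretrained: SleepStager, train_nights, val_nights,
              sched: LRSchedule, lr_scale: float = 0.1, seed: int = 0,
              n_classes: int | None = None, momentum: float = 0.9,
              n_epochs: int | None = None) -> tuple[SleepStager, TrainingHistory]:
    """Continue training from pretrained weights at reduced learning rates.

    All schedule rates are multiplied by ``lr_scale`` (0 < scale <= 1).  If
    the target class count differs from the pretrained head, the output layer
    is re-initialized (and a warning is emitted); all other weights carry
    over.
    """
    if not 0 < lr_scale <= 1:
        raise ValueError("lr_scale must be in (0, 1]")
    target_classes = n_classes or pretrained.n_classes
    model = SleepStager(pretrained.spec, n_classes=target_classes, seed=seed)
    mismatch = target_classes != pretrained.n_classes
    if mismatch:
        warnings.warn(
            f"class-count mismatch ({pretrained.n_classes} -> {target_classes}); "
            "output head re-initialized")
    model.copy_weights_from(pretrained, skip_output=mismatch)
    history = train(model, train_nights, val_nights, sched, seed=seed,
                    momentum=momentum, lr_scale=lr_scale, n_epochs=n_epochs)
    return model, history


def model_step_fn(model: SleepStager, nights, momentum: float = 0.9):
    """Adapt a model + night list into the ``step_fn`` of the range test."""
    opt = SGD(model.parameters(), momentum=momentum)
    state = {"i": 0}

    def step(lr: float) -> float:
        windows, labels = nights[state["i"] % len(nights)]
        state["i"] += 1
        loss = model.loss_and_gradients(windows, labels)
        opt.step(lr)
        return loss

    return step
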