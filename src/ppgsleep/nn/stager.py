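"""The PPG sleep-staging network: per-epoch 1D CNN -> BiLSTM -> dense head.

The feature extractor is a 1D EfficientNet: a strided stem convolution,
seven stages of MBConv blocks, and a 1x1 convolution to the feature width
followed by global average pooling.  It is applied independently to each
30-s epoch (960 samples at 32 Hz); a bidirectional LSTM then integrates the
whole night of epoch features in both time directions, and two dense layers
(ReLU, then softmax) emit one stage-probability vector per epoch.

``default_spec()`` reproduces the published block configuration exactly,
including its component parameter counts; ``compact_spec()`` is a
width/depth-reduced variant of the same design for CPU-scale experiments.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import (
    BatchNorm1d,
    Conv1d,
    GlobalAvgPool1d,
    MBConv,
    ReLU,
    Sequential,
    Swish,
    conv_output_length,
)
from .lstm import BiLSTM
from ..preprocess import SAMPLES_PER_EPOCH

__all__ = [
    "BlockSpec",
    "StagerSpec",
    "SleepStager",
    "default_spec",
    "compact_spec",
    "CLASS_ORDER",
    "stem_output_length",
]

#: Fixed label order of the 5-class output head; argmax ties break low.
CLASS_ORDER = {
    5: ("W", "N1", "N2", "N3", "R"),
    4: ("W", "LIGHT", "N3", "R"),
    3: ("W", "NREM", "R"),
}


@dataclass(frozen=True)
class BlockSpec:
    kernel: int
    stride: int
    channels: int
    expand_ratio: int
    repeats: int
    se_ratio: float = 0.25


@dataclass(frozen=True)
class StagerSpec:
    input_len: int = SAMPLES_PER_EPOCH
    stem_kernel: int = 11
    stem_stride: int = 3
    stem_channels: int = 32
    blocks: tuple[BlockSpec, ...] = ()
    head_channels: int = 512
    lstm_units: int = 128
    dense_units: int = 32


def default_spec() -> StagerSpec:
    """The published architecture (CNN 696,156 / BiLSTM 656,384 params)."""
    return StagerSpec(
        blocks=(
            BlockSpec(3, 1, 16, 1, 1),
            BlockSpec(5, 2, 24, 6, 2),
            BlockSpec(3, 2, 24, 6, 2),
            BlockSpec(5, 2, 32, 6, 3),
            BlockSpec(5, 2, 48, 6, 4),
            BlockSpec(5, 2, 64, 6, 5),
            BlockSpec(3, 1, 128, 6, 1),
        ),
    )


def compact_spec() -> StagerSpec:
    """Width/depth-reduced variant for CPU-scale training experiments."""
    return StagerSpec(
        stem_channels=8,
        blocks=(
            BlockSpec(3, 1, 8, 1, 1),
            BlockSpec(5, 2, 16, 4, 1),
            BlockSpec(5, 2, 24, 4, 1),
            BlockSpec(3, 2, 32, 4, 1),
        ),
        head_channels=64,
        lstm_units=32,
        dense_units=16,
    )


def stem_output_length(input_len: int, kernel: int = 11, stride: int = 3) -> int:
    """Output length of the unpadded stem convolution (floor((L-k)/s)+1)."""
    if input_len < kernel:
        raise ValueError(f"input length {input_len} shorter than kernel {kernel}")
    return (input_len - kernel) // stride + 1


class SleepStager:
    """Sleep-staging model; built untrained, weights adjusted by training.

    Parameters
    ----------
    spec
        Architecture description; ``default_spec()`` if omitted.
    n_classes
        3 (W/NREM/R), 4 (W/N1+N2/N3/R) or 5 (W/N1/N2/N3/R).
    seed
        Weight-initialization seed.
    """

    def __init__(self, spec: StagerSpec | None = None, n_classes: int = 5,
                 seed: int = 0):
        if n_classes not in (3, 4, 5):
            raise ValueError(f"n_classes must be 3, 4 or 5, got {n_classes}")
        self.spec = spec or default_spec()
        self.n_classes = n_classes
        self.class_order = CLASS_ORDER[n_classes]
        rng = np.random.default_rng(seed)
        self._build(rng)

    # -- construction ----------------------------------------------------
    def _build(self, rng):
        from .core import Dense  # local: avoid shadowing by module attr

        s = self.spec
        layers = [
            Conv1d(1, s.stem_channels, s.stem_kernel, s.stem_stride,
                   padding="valid", rng=rng, name="stem"),
            BatchNorm1d(s.stem_channels, name="stem_bn"),
            Swish(),
        ]
        cin = s.stem_channels
        for bi, blk in enumerate(s.blocks):
            for r in range(blk.repeats):
                stride = blk.stride if r == 0 else 1
                layers.append(MBConv(cin, blk.channels, blk.kernel, stride,
                                     blk.expand_ratio, blk.se_ratio, rng=rng,
                                     name=f"mb{bi + 1}.{r}"))
                cin = blk.channels
        layers += [
            Conv1d(cin, s.head_channels, 1, 1, "same", rng=rng, name="head"),
            BatchNorm1d(s.head_channels, name="head_bn"),
            Swish(),
            GlobalAvgPool1d(),
        ]
        self.cnn = Sequential(layers)
        self.rnn = BiLSTM(s.head_channels, s.lstm_units, rng=rng, name="bilstm")
        self.dense = Dense(2 * s.lstm_units, s.dense_units, rng=rng, name="dense")
        self.dense_act = ReLU()
        self.output = Dense(s.dense_units, self.n_classes, rng=rng, name="output")

    # -- bookkeeping -----------------------------------------------------
    def components(self):
        return {
            "cnn": self.cnn,
            "rnn": self.rnn,
            "dense": self.dense,
            "output": self.output,
        }

    def count_parameters(self, component: str = "total") -> int:
        """Parameter count of a component ('cnn', 'rnn', 'dense', 'output',
        'total'), counting batch-norm moving statistics."""
        comps = self.components()
        if component == "total":
            return sum(c.n_params() for c in comps.values())
        if component not in comps:
            raise KeyError(f"unknown component {component!r}")
        return comps[component].n_params()

    def resolution_trace(self) -> list[int]:
        """Input length seen by the stem, each MBConv stage, and the head."""
        s = self.spec
        trace = [s.input_len]
        L = conv_output_length(s.input_len, s.stem_kernel, s.stem_stride, "valid")
        for blk in s.blocks:
            trace.append(L)
            L = conv_output_length(L, blk.kernel, blk.stride, "same")
            # later repeats have stride 1 and leave the length unchanged
        trace.append(L)
        return trace

    def describe(self) -> str:
        lines = [f"{'component':<10} {'output':>12} {'#params':>10}"]
        shapes = {
            "cnn": f"(Any, {self.spec.head_channels})",
            "rnn": f"(Any, {2 * self.spec.lstm_units})",
            "dense": f"(Any, {self.spec.dense_units})",
            "output": f"(Any, {self.n_classes})",
        }
        for name in ("cnn", "rnn", "dense", "output"):
            lines.append(f"{name:<10} {shapes[name]:>12} "
                         f"{self.count_parameters(name):>10,}")
        lines.append(f"{'total':<10} {'':>12} {self.count_parameters():>10,}")
        return "\n".join(lines)

    def parameters(self):
        return [p for c in self.components().values() for p in c.parameters()]

    # -- forward ---------------------------------------------------------
    def _check_windows(self, windows):
        w = np.asarray(windows, dtype=np.float64)
        if w.ndim == 2:
            w = w[:, :, None]
        if w.shape[0] == 0:
            raise ValueError("empty epoch sequence")
        if w.shape[1] != self.spec.input_len:
            raise ValueError(
                f"windows must have {self.spec.input_len} samples, got {w.shape[1]}")
        return w

    def forward(self, windows, train=False, chunk=256):
        """Per-epoch class probabilities for a night of epochs.

        Parameters
        ----------
        windows : array (n_epochs, 960) or (n_epochs, 960, 1)

        Returns
        -------
        array (n_epochs, n_classes), rows summing to one.
        """
        logits = self._logits(windows, train=train, chunk=chunk)
        return _softmax(logits)

    def _logits(self, windows, train=False, chunk=256):
        w = self._check_windows(windows)
        if train:
            feats = self.cnn.forward(w, train=True)
        else:
            feats = np.concatenate([
                self.cnn.forward(w[i : i + chunk]) for i in range(0, len(w), chunk)
            ])
        h = self.rnn.forward(feats, train=train)
        h = self.dense_act.forward(self.dense.forward(h, train=train), train=train)
        return self.output.forward(h, train=train)

    def predict_stages(self, windows) -> np.ndarray:
        """Argmax stage labels (ties break toward the lower class index)."""
        probs = self.forward(windows)
        idx = probs.argmax(axis=1)
        return np.asarray([self.class_order[i] for i in idx])

    # -- training step ---------------------------------------------------
    def loss_and_gradients(self, windows, labels) -> float:
        """Mean cross-entropy on one night; accumulates parameter gradients."""
        labels = np.asarray(labels)
        logits = self._logits(windows, train=True)
        probs = _softmax(logits)
        n = len(labels)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(n), labels] + eps))
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        dh = self.output.backward(dlogits)
        dh = self.dense.backward(self.dense_act.backward(dh))
        dfeats = self.rnn.backward(dh)
        self.cnn.backward(dfeats)
        return float(loss)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[:] = 0.0

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """Single-file checkpoint (spec + weights + BN statistics)."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        bufs = [b for c in self.components().values() for b in c.buffers()]
        arrays.update({f"b{i}": b for i, b in enumerate(bufs)})
        meta = json.dumps({
            "n_classes": self.n_classes,
            "spec": {**asdict(self.spec),
                     "blocks": [asdict(b) for b in self.spec.blocks]},
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SleepStager":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec_d = dict(meta["spec"])
            spec_d["blocks"] = tuple(BlockSpec(**b) for b in spec_d["blocks"])
            model = cls(StagerSpec(**spec_d), n_classes=meta["n_classes"])
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"p{i}"]
            bufs = [b for c in model.components().values() for b in c.buffers()]
            for i, b in enumerate(bufs):
                b[...] = data[f"b{i}"]
        return model

    def copy_weights_from(self, other: "SleepStager", skip_output=False):
        """In-place weight copy from a model with the same spec."""
        mine, theirs = self.parameters(), other.parameters()
        n_out = len(self.output.parameters())
        for i, (p, q) in enumerate(zip(mine, theirs)):
            if skip_output and i >= len(mine) - n_out:
                continue
            p.value[...] = q.value
        for b, c in zip(
            [b for comp in self.components().values() for b in comp.buffers()],
            [b for comp in other.components().values() for b in comp.buffers()],
        ):
            b[...] = c


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
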