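"""Hypnograms: stage sequences on a fixed epoch grid, and their comparison.

A hypnogram holds one stage label per epoch-to-epoch interval ``d`` (30, 15,
5 or 1 s); each label is attributed to the leading ``d`` seconds of its 30-s
scoring window, so label ``i`` covers ``[i*d, i*d + d)``.  Schemes are the
5-class AASM set (W/N1/N2/N3/R), its 4-class merge (N1+N2 -> LIGHT) and the
3-class merge (all NREM together); the older R&K scheme (S1..S4) maps onto
AASM by merging S3 and S4 into N3.  Only merges are possible — a coarse
hypnogram cannot be split back into finer stages.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, \
    precision_recall_fscore_support

from .preprocess import EPOCH_LEN_S, VALID_INTERVALS, PPGRecording, prepare_epochs

__all__ = [
    "SCHEMES",
    "Hypnogram",
    "AgreementReport",
    "map_scheme",
    "agreement",
    "predict_hypnogram",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
]

SCHEMES: dict[int | str, tuple[str, ...]] = {
    5: ("W", "N1", "N2", "N3", "R"),
    4: ("W", "LIGHT", "N3", "R"),
    3: ("W", "NREM", "R"),
    "rk": ("W", "S1", "S2", "S3", "S4", "R"),
}

# target scheme -> mapping applied to 5-class labels
_MERGE_FROM_5 = {
    5: {},
    4: {"N1": "LIGHT", "N2": "LIGHT"},
    3: {"N1": "NREM", "N2": "NREM", "N3": "NREM"},
}
_RK_TO_AASM = {"S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3"}


@dataclass
class Hypnogram:
    """Stage labels on a regular grid of overlapping-or-not 30-s windows."""

    stages: np.ndarray
    interval_s: int
    scheme: int | str = 5
    epoch_len_s: int = EPOCH_LEN_S
    start_offset_s: float = 0.0
    patient_id: str = ""

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype="U8")
        if self.interval_s not in VALID_INTERVALS:
            raise ValueError(f"interval must be one of {VALID_INTERVALS}")
        allowed = set(SCHEMES[self.scheme])
        bad = set(self.stages.tolist()) - allowed
        if bad:
            raise ValueError(f"labels {sorted(bad)} not in scheme {self.scheme}")

    def __len__(self):
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        """Span covered by labels (the trailing 30 - d s carry no label)."""
        return len(self.stages) * self.interval_s

    def wake_mask(self) -> np.ndarray:
        return self.stages == "W"


def map_scheme(h: Hypnogram, target: int) -> Hypnogram:
    """Merge a hypnogram into a coarser scheme (splits are rejected).

    5 -> 4 merges N1 and N2 into LIGHT; 5 -> 3 merges all NREM stages;
    the R&K scheme maps to 5-class AASM by merging S3 and S4 into N3.
    W and R are always preserved.
    """
    if target not in (3, 4, 5):
        raise ValueError(f"target scheme must be 3, 4 or 5, got {target!r}")
    if h.scheme == "rk":
        stages = np.asarray([_RK_TO_AASM.get(s, s) for s in h.stages])
        h = Hypnogram(stages, h.interval_s, 5, h.epoch_len_s, h.start_offset_s,
                      h.patient_id)
    if target == h.scheme:
        return Hypnogram(h.stages.copy(), h.interval_s, h.scheme, h.epoch_len_s,
                         h.start_offset_s, h.patient_id)
    if target > h.scheme:
        raise ValueError(f"cannot split a {h.scheme}-class hypnogram to {target}")
    if h.scheme == 4:
        merge = {"LIGHT": "NREM", "N3": "NREM"}
    else:
        merge = _MERGE_FROM_5[target]
    stages = np.asarray([merge.get(s, s) for s in h.stages])
    return Hypnogram(stages, h.interval_s, target, h.epoch_len_s,
                     h.start_offset_s, h.patient_id)


@dataclass
class AgreementReport:
    """Confusion-matrix agreement between a reference and a test scoring."""

    labels: tuple[str, ...]
    confusion: np.ndarray  # reference on rows
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    kappa: float
    n: int
    absent_classes: tuple[str, ...] = ()

    def macro_f1(self) -> float:
        vals = [v for k, v in self.f1.items() if k not in self.absent_classes]
        return float(np.mean(vals))

    def to_json(self) -> str:
        return json.dumps({
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "n": self.n,
            "absent_classes": list(self.absent_classes),
        }, indent=2)


def _align(ref: Hypnogram, test: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
    """Bring two hypnograms onto a common grid.

    If the intervals differ by an integer factor, the coarser hypnogram is
    upsampled by label repetition; the sequences are then truncated to their
    common length.
    """
    a, b = ref, test
    if a.interval_s != b.interval_s:
        coarse, fine = (a, b) if a.interval_s > b.interval_s else (b, a)
        factor = coarse.interval_s / fine.interval_s
        if factor != int(factor):
            raise ValueError(
                f"intervals {a.interval_s} and {b.interval_s} are incommensurate")
        rep = np.repeat(coarse.stages, int(factor))
        sa, sb = (rep, b.stages) if coarse is a else (a.stages, rep)
    else:
        sa, sb = a.stages, b.stages
    n = min(len(sa), len(sb))
    if n == 0:
        raise ValueError("no overlapping epochs to compare")
    return sa[:n], sb[:n]


def agreement(ref: Hypnogram, test: Hypnogram) -> AgreementReport:
    """Epoch-wise agreement metrics (reference on confusion rows).

    Cohen's kappa uses the marginal-product expected agreement.  Classes
    absent from both scorings get undefined per-class scores and are listed
    in ``absent_classes`` (excluded from macro summaries).
    """
    if ref.scheme != test.scheme:
        raise ValueError(f"scheme mismatch: {ref.scheme} vs {test.scheme}")
    sa, sb = _align(ref, test)
    labels = list(SCHEMES[ref.scheme])
    conf = confusion_matrix(sa, sb, labels=labels)
    n = int(conf.sum())
    acc = float(np.trace(conf)) / n
    prec, rec, f1, _ = precision_recall_fscore_support(
        sa, sb, labels=labels, zero_division=0)
    if len(set(sa) | set(sb)) > 1:
        kappa = float(cohen_kappa_score(sa, sb, labels=labels))
    else:
        kappa = 1.0 if acc == 1.0 else 0.0
    absent = tuple(l for i, l in enumerate(labels)
                   if conf[i].sum() == 0 and conf[:, i].sum() == 0)
    return AgreementReport(
        labels=tuple(labels),
        confusion=conf,
        accuracy=acc,
        precision={l: float(p) for l, p in zip(labels, prec)},
        recall={l: float(r) for l, r in zip(labels, rec)},
        f1={l: float(v) for l, v in zip(labels, f1)},
        kappa=kappa,
        n=n,
        absent_classes=absent,
    )


def predict_hypnogram(model, rec: PPGRecording, interval_s: int = 30) -> Hypnogram:
    """Run the full inference pipeline on a raw recording.

    The recording is downsampled to 32 Hz, z-scored, cut into 30-s windows
    every ``interval_s`` seconds, and staged by the model; window ``i``'s
    argmax stage is attributed to ``[i*d, i*d + d)``.

    For ``d`` < 30 the window grid is processed as ``30/d`` interleaved
    subsequences, one per phase offset, each spaced 30 s apart — the epoch
    spacing the recurrent layer is trained on.  The 30-s hypnogram is then an
    exact subsequence of any finer one (identical labels at shared windows).
    """
    epochs = prepare_epochs(rec, interval_s)
    n = epochs.n_epochs
    stages = np.empty(n, dtype="U8")
    k = EPOCH_LEN_S // interval_s
    for j in range(k):
        idx = np.arange(j, n, k)
        stages[idx] = model.predict_stages(epochs.windows[idx])
    return Hypnogram(stages, interval_s, scheme=model.n_classes,
                     patient_id=rec.patient_id)


def write_hypnogram_csv(path, h: Hypnogram) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "start_s", "duration_s", "stage"])
        for i, s in enumerate(h.stages):
            w.writerow([i, i * h.interval_s + h.start_offset_s, h.interval_s, s])


def read_hypnogram_csv(path, scheme: int | str = 5,
                       patient_id: str = "") -> Hypnogram:
    rows = list(csv.DictReader(open(path)))
    if not rows:
        raise ValueError(f"empty hypnogram file {path}")
    interval = int(float(rows[0]["duration_s"]))
    stages = [r["stage"] for r in rows]
    return Hypnogram(np.asarray(stages), interval, scheme,
                     start_offset_s=float(rows[0]["start_s"]),
                     patient_id=patient_id)
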