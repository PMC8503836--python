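"""Synthetic sleep cohorts: dense stage sequences and stage-dependent PPG.

The paper's substance is measured on clinical recordings that cannot be
shared, so this module generates seeded stand-ins with the two properties the
downstream analyses rely on:

* **Fragmentation structure.**  Nights are semi-Markov bout processes over
  {W, N1, N2, N3, R} with exponential bout durations following the typical
  cycle order, beginning with a wake-to-sleep onset segment.  On top of the
  bout process, a Poisson process injects brief wake intrusions at a rate
  that increases with OSA severity, so higher severity yields shorter runs
  of continuous sleep.  Intrusions are often shorter than a 30-s scoring
  epoch, which is exactly the regime where densified hypnograms matter.

* **Stage-separable pulse statistics.**  The PPG is a train of stereotyped
  two-Gaussian pulses whose inter-beat interval, beat-to-beat variability and
  amplitude depend on the current stage, with a respiratory baseline
  oscillation and movement-artifact bursts during wake.  REM and wake have
  larger beat-interval variability than deep sleep, mimicking the sympathetic
  bursts of REM; no respiratory-event waveforms or SpO2 are modelled.

All numeric defaults are the package's own choices (documented in the
methods note); the source publication states no quantitative physiology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .hypnogram import Hypnogram
from .preprocess import PPGRecording

__all__ = [
    "STAGES",
    "CATEGORIES",
    "StagePhysiology",
    "DEFAULT_PHYSIOLOGY",
    "CohortSpec",
    "PatientRecord",
    "simulate_stage_sequence",
    "simulate_ppg",
    "simulate_cohort",
    "densify_truth",
    "majority_label",
]

STAGES = ("W", "N1", "N2", "N3", "R")
CATEGORIES = ("no", "mild", "moderate", "severe")
_CODE = {s: i for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class StagePhysiology:
    """Pulse statistics of one sleep stage.

    mean_ibi/ibi_sd in seconds, pulse_amp in arbitrary units, resp_rate in Hz
    (baseline modulation), artifact_rate in events/min (movement bursts,
    nonzero only during wake).
    """

    stage: str
    mean_ibi: float
    ibi_sd: float
    pulse_amp: float
    resp_rate: float
    artifact_rate: float = 0.0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.mean_ibi <= 0 or self.pulse_amp <= 0:
            raise ValueError("mean_ibi and pulse_amp must be positive")
        if self.ibi_sd < 0 or self.resp_rate <= 0 or self.artifact_rate < 0:
            raise ValueError("invalid physiology values")


#: Default stage physiology.  Heart rate slows and steadies from wake into
#: deep sleep and speeds up again in REM; pulse amplitude grows with vagal
#: dominance; wake and REM carry the largest beat-to-beat variability.
DEFAULT_PHYSIOLOGY: dict[str, StagePhysiology] = {
    "W": StagePhysiology("W", 0.85, 0.070, 1.00, 0.25, artifact_rate=3.0),
    "N1": StagePhysiology("N1", 0.95, 0.050, 1.10, 0.23),
    "N2": StagePhysiology("N2", 1.00, 0.040, 1.20, 0.21),
    "N3": StagePhysiology("N3", 1.05, 0.020, 1.30, 0.19),
    "R": StagePhysiology("R", 0.88, 0.080, 0.95, 0.26),
}

#: Stage-bout transition probabilities of the semi-Markov process, following
#: the typical cycle order W -> N1 -> N2 -> N3 -> N2 -> R.
_TRANSITIONS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "W": (("N1",), (1.0,)),
    "N1": (("N2", "W", "R"), (0.85, 0.10, 0.05)),
    "N2": (("N3", "R", "N1", "W"), (0.50, 0.30, 0.10, 0.10)),
    "N3": (("N2", "W"), (0.85, 0.15)),
    "R": (("N1", "N2", "W"), (0.40, 0.40, 0.20)),
}

#: Mean bout durations in seconds (exponential draws, floored at 30 s).
DEFAULT_BOUT_MEANS_S: dict[str, float] = {
    "W": 120.0, "N1": 120.0, "N2": 720.0, "N3": 720.0, "R": 900.0,
}

#: Wake-intrusion rates (events/h) per OSA severity; strictly increasing.
DEFAULT_INTRUSION_RATES: dict[str, float] = {
    "no": 2.0, "mild": 8.0, "moderate": 20.0, "severe": 40.0,
}

#: AHI sampling intervals per category (events/h), respecting the clinical
#: thresholds 5 / 15 / 30.
DEFAULT_AHI_RANGES: dict[str, tuple[float, float]] = {
    "no": (0.0, 5.0), "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0), "severe": (30.0, 60.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort."""

    n_per_category: tuple[int, int, int, int] = (5, 5, 5, 5)
    duration_s: float = 28800.0
    wake_intrusion_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTRUSION_RATES))
    intrusion_duration_s: float = 15.0
    bout_means_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BOUT_MEANS_S))
    ahi_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AHI_RANGES))
    rate_dispersion: float = 0.6
    onset_latency_s: float = 600.0
    ppg_fs: float = 256.0
    physiology: dict[str, StagePhysiology] = field(
        default_factory=lambda: dict(DEFAULT_PHYSIOLOGY))
    seed: int = 0

    def __post_init__(self):
        rates = [self.wake_intrusion_rate[c] for c in CATEGORIES]
        if not all(a < b for a, b in zip(rates, rates[1:])):
            raise ValueError("intrusion rates must strictly increase with severity")
        for c, (lo, hi) in self.ahi_ranges.items():
            if lo >= hi or lo < 0:
                raise ValueError(f"bad AHI range for {c}: ({lo}, {hi})")


@dataclass
class PatientRecord:
    """One simulated night: waveform, truths, severity metadata."""

    patient_id: str
    category: str
    ahi: float
    dense_stages: np.ndarray  # 1-s labels, dtype U2
    hypnogram_30s: Hypnogram
    ppg: PPGRecording | None
    seed: int


def simulate_stage_sequence(spec: CohortSpec, category: str,
                            rng_seed: int) -> np.ndarray:
    """Dense (1-s) stage labels for one night of the given severity.

    A wake onset segment is followed by a semi-Markov bout process; wake
    intrusions then overwrite sleep at the category's Poisson rate.  Same
    seed, same spec -> identical sequence.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    T = int(spec.duration_s)
    if T < 3600:
        raise ValueError("night duration must be at least 3600 s")
    rng = np.random.default_rng(rng_seed)
    seq = np.empty(T, dtype="U2")

    # wake-to-sleep onset segment
    onset = int(np.clip(rng.exponential(spec.onset_latency_s), 60, T - 1800))
    seq[:onset] = "W"
    t, stage = onset, "N1"
    while t < T:
        bout = max(30.0, rng.exponential(spec.bout_means_s[stage]))
        end = min(T, t + int(round(bout)))
        seq[t:end] = stage
        t = end
        nxt, probs = _TRANSITIONS[stage]
        stage = nxt[rng.choice(len(nxt), p=probs)]

    # Poisson wake intrusions after sleep onset; the category rate is the
    # night's median tendency, with mean-one lognormal patient-to-patient
    # dispersion so severity distributions overlap as clinical ones do
    lam = spec.wake_intrusion_rate[category]
    if spec.rate_dispersion > 0:
        sig = spec.rate_dispersion
        lam *= rng.lognormal(-0.5 * sig * sig, sig)
    hours = (T - onset) / 3600.0
    n_intr = rng.poisson(lam * hours)
    if n_intr:
        starts = np.sort(rng.uniform(onset, T, size=n_intr))
        durs = np.maximum(2.0, rng.exponential(spec.intrusion_duration_s,
                                               size=n_intr))
        for s, d in zip(starts, durs):
            seq[int(s):min(T, int(s + d))] = "W"
    return seq


def _pulse_shape(ibi: float, fs: float) -> np.ndarray:
    """Stereotyped beat: systolic peak plus a smaller dicrotic hump."""
    n = max(2, int(round(ibi * fs)))
    tau = np.arange(n) / fs
    return (np.exp(-0.5 * ((tau - 0.20) / 0.045) ** 2)
            + 0.35 * np.exp(-0.5 * ((tau - 0.45) / 0.090) ** 2))


def simulate_ppg(stages: np.ndarray, physiology: dict[str, StagePhysiology]
                 | None = None, fs: float = 256.0, rng_seed: int = 0,
                 patient_id: str = "") -> PPGRecording:
    """Render a PPG waveform for a dense (1-s) stage sequence.

    Beats are placed sequentially with stage-dependent inter-beat intervals
    and amplitudes, on top of a respiratory baseline whose frequency follows
    the stage; wake segments receive movement-artifact bursts.  Output length
    is exactly ``len(stages) * fs`` samples.
    """
    physiology = physiology if physiology is not None else DEFAULT_PHYSIOLOGY
    stages = np.asarray(stages, dtype="U2")
    missing = set(stages.tolist()) - set(physiology)
    if missing:
        raise KeyError(f"no physiology for stages {sorted(missing)}")
    if fs < 64:
        raise ValueError("fs below twice the pulse bandwidth (need >= 64 Hz)")
    rng = np.random.default_rng(rng_seed)
    T = len(stages)
    n = int(round(T * fs))
    x = np.zeros(n)

    # beat train
    t = float(rng.uniform(0.0, 0.5))
    while t < T:
        phys = physiology[stages[min(int(t), T - 1)]]
        ibi = float(np.clip(rng.normal(phys.mean_ibi, phys.ibi_sd), 0.4, 2.0))
        amp = phys.pulse_amp * (1.0 + 0.05 * rng.normal())
        beat = amp * _pulse_shape(ibi, fs)
        i0 = int(round(t * fs))
        i1 = min(n, i0 + len(beat))
        x[i0:i1] += beat[: i1 - i0]
        t += ibi

    # respiratory baseline: frequency tracks the stage, phase is continuous
    resp_f = np.asarray([physiology[s].resp_rate for s in stages])
    f_per_sample = np.repeat(resp_f, int(round(fs)))[:n]
    phase = np.cumsum(2.0 * np.pi * f_per_sample / fs)
    x += 0.25 * np.sin(phase)

    # movement-artifact bursts during wake
    for stage in set(stages.tolist()):
        rate = physiology[stage].artifact_rate
        if rate <= 0:
            continue
        mask = stages == stage
        total_min = mask.sum() / 60.0
        n_events = rng.poisson(rate * total_min)
        if n_events == 0:
            continue
        positions = np.flatnonzero(mask)
        starts = rng.choice(positions, size=n_events)
        for s in starts:
            i0 = int(s * fs)
            i1 = min(n, i0 + int(2.0 * fs))
            x[i0:i1] += 3.0 * rng.normal(size=i1 - i0)

    x += 0.05 * rng.normal(size=n)
    return PPGRecording(x, fs, patient_id=patient_id)


def majority_label(window: np.ndarray) -> str:
    """Most frequent label; ties break toward the earlier-starting label."""
    labels, first_idx, counts = np.unique(np.asarray(window, dtype="U2"),
                                          return_index=True, return_counts=True)
    best = counts.max()
    cand = counts == best
    return str(labels[cand][np.argmin(first_idx[cand])])


def densify_truth(dense: np.ndarray, interval_s: int,
                  epoch_len_s: int = 30, patient_id: str = "") -> Hypnogram:
    """Score a dense 1-s truth on the epoch grid of step ``interval_s``.

    Each 30-s window starting at ``i * d`` gets its majority-vote label, the
    same windowing the staging model sees.  This is the model-free "virtual
    scorer" used for densification experiments on synthetic truth.
    """
    dense = np.asarray(dense, dtype="U2")
    T = len(dense)
    n = (T - epoch_len_s) // interval_s + 1
    if n < 1:
        raise ValueError("sequence shorter than one epoch")
    stages = np.empty(n, dtype="U2")
    for i in range(n):
        s = i * interval_s
        stages[i] = majority_label(dense[s : s + epoch_len_s])
    return Hypnogram(stages, interval_s, scheme=5, patient_id=patient_id)


def simulate_cohort(spec: CohortSpec, with_ppg: bool = True
                    ) -> list[PatientRecord]:
    """Simulate a full cohort; deterministic in ``spec.seed``.

    Per patient: dense 1-s truth, its 30-s majority-vote hypnogram, an AHI
    drawn from the category's range, and (optionally) the PPG waveform.
    """
    if any(n <= 0 for n in spec.n_per_category):
        raise ValueError("each category needs at least one patient")
    root = np.random.SeedSequence(spec.seed)
    records = []
    pid = 0
    for cat, n_cat in zip(CATEGORIES, spec.n_per_category):
        for _ in range(n_cat):
            child = root.spawn(1)[0]
            seeds = child.generate_state(3)
            meta_rng = np.random.default_rng(seeds[0])
            ahi = float(meta_rng.uniform(*spec.ahi_ranges[cat]))
            dense = simulate_stage_sequence(spec, cat, int(seeds[1] >> 1))
            hyp = densify_truth(dense, 30, patient_id=f"p{pid:03d}")
            ppg = None
            if with_ppg:
                ppg = simulate_ppg(dense, spec.physiology, spec.ppg_fs,
                                   int(seeds[2] >> 1), patient_id=f"p{pid:03d}")
            records.append(PatientRecord(
                patient_id=f"p{pid:03d}", category=cat, ahi=ahi,
                dense_stages=dense, hypnogram_30s=hyp, ppg=ppg,
                seed=int(seeds[1] >> 1)))
            pid += 1
    return records


def training_windows(record: PatientRecord, n_classes: int = 5):
    """Model-ready (windows, integer labels) for one simulated night.

    Non-overlapping 30-s epochs, labels from the majority-vote truth mapped
    to the class scheme.
    """
    from .hypnogram import map_scheme
    from .nn.stager import CLASS_ORDER
    from .preprocess import prepare_epochs

    epochs = prepare_epochs(record.ppg, 30)
    hyp = map_scheme(record.hypnogram_30s, n_classes)
    order = {s: i for i, s in enumerate(CLASS_ORDER[n_classes])}
    n = min(epochs.n_epochs, len(hyp.stages))
    labels = np.asarray([order[s] for s in hyp.stages[:n]])
    return epochs.windows[:n], labels
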