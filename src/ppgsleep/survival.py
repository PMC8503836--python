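"""Sleep-fragmentation survival analysis.

Continuous sleep is any maximal run of consecutive non-wake epochs; its mean
length per patient is the "time to event" of a Cox proportional-hazards
model with one-hot OSA-severity covariates (non-OSA as reference, every
patient an event, no censoring).  Kaplan-Meier curves per category give the
fraction of patients whose mean continuous sleep exceeds a given duration.
Fits go through lifelines with Efron tie handling; confidence bands are the
log-log (exponential) Greenwood intervals lifelines computes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .hypnogram import Hypnogram

__all__ = [
    "CATEGORIES",
    "osa_category",
    "extract_sleep_runs",
    "mean_continuous_sleep",
    "SurvivalTable",
    "build_survival_table",
    "CoxResult",
    "cox_fit",
    "KMCurve",
    "km_estimate",
    "FragmentationResult",
    "fragmentation_analysis",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("no", "mild", "moderate", "severe")
_COVARIATES = ("mild", "moderate", "severe")


def osa_category(ahi: float) -> str:
    """OSA severity from the AHI: <5 none, 5-15 mild, 15-30 moderate, >=30 severe."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    if ahi < 5:
        return "no"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def extract_sleep_runs(h: Hypnogram) -> np.ndarray:
    """Durations (minutes) of maximal runs of consecutive non-wake labels.

    Runs touching the recording edges are included; an all-wake hypnogram
    yields an empty array.
    """
    sleep = ~h.wake_mask()
    if not sleep.any():
        return np.empty(0)
    padded = np.concatenate([[False], sleep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return (ends - starts) * h.interval_s / 60.0


def mean_continuous_sleep(runs) -> float:
    """Arithmetic mean run duration; undefined (error) without any run."""
    runs = np.asarray(runs, dtype=float)
    if runs.size == 0:
        raise ValueError("patient has no sleep runs; mean undefined")
    return float(runs.mean())


@dataclass
class SurvivalTable:
    """Per-patient mean continuous sleep with one-hot severity covariates."""

    frame: pd.DataFrame  # patient_id, duration_min, category, mild, moderate, severe, event

    def __len__(self):
        return len(self.frame)


def build_survival_table(patient_ids, durations_min, categories) -> SurvivalTable:
    frame = pd.DataFrame({
        "patient_id": list(patient_ids),
        "duration_min": np.asarray(durations_min, dtype=float),
        "category": list(categories),
    })
    bad = set(frame["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    if (frame["duration_min"] <= 0).any():
        raise ValueError("durations must be positive")
    for cov in _COVARIATES:
        frame[cov] = (frame["category"] == cov).astype(float)
    frame["event"] = 1
    return SurvivalTable(frame)


@dataclass
class CoxResult:
    """Hazard ratios for ending continuous sleep vs the non-OSA reference."""

    beta: dict[str, float]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p: dict[str, float]
    loglik: float
    n: int

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta, "hr": self.hr,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "p": self.p, "loglik": self.loglik, "n": self.n,
        }, indent=2)


def cox_fit(table: SurvivalTable) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, all events)."""
    frame = table.frame
    present = [c for c in CATEGORIES if (frame["category"] == c).any()]
    if len(present) < 2 or any((frame["category"] == c).sum() < 2
                               for c in present):
        raise ValueError("need >= 2 categories with >= 2 patients each")
    covs = [c for c in _COVARIATES if (frame["category"] == c).any()]
    cph = CoxPHFitter()
    try:
        cph.fit(frame[["duration_min", "event"] + covs],
                duration_col="duration_min", event_col="event",
                fit_options={"precision": 1e-9})
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    summary = cph.summary
    ci = {c: (float(np.exp(summary.loc[c, "coef lower 95%"])),
              float(np.exp(summary.loc[c, "coef upper 95%"])))
          for c in covs}
    return CoxResult(
        beta={c: float(summary.loc[c, "coef"]) for c in covs},
        hr={c: float(np.exp(summary.loc[c, "coef"])) for c in covs},
        ci95=ci,
        p={c: float(summary.loc[c, "p"]) for c in covs},
        loglik=float(cph.log_likelihood_),
        n=len(frame),
    )


@dataclass
class KMCurve:
    """Product-limit survival curve with 95% confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(durations_min, label: str = "") -> KMCurve:
    """Kaplan-Meier estimate of P(mean continuous sleep > t); all events."""
    durations = np.asarray(durations_min, dtype=float)
    if durations.size == 0:
        raise ValueError("no durations")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=np.ones_like(durations), label=label or "km")
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_lo=ci.iloc[:, 0].to_numpy(),
        ci_hi=ci.iloc[:, 1].to_numpy(),
        label=label,
    )


@dataclass
class FragmentationResult:
    interval_s: int
    table: SurvivalTable
    cox: CoxResult
    km: dict[str, KMCurve]
    excluded: tuple[str, ...]


def fragmentation_analysis(
    hypnograms_by_interval: dict[int, list[Hypnogram]],
    ahi_by_patient: dict[str, float],
    intervals: tuple[int, ...] = (30, 15, 5),
) -> dict[int, FragmentationResult]:
    """The full fragmentation pipeline over several epoch intervals.

    For each interval: per-patient mean continuous sleep from the supplied
    hypnograms (model-predicted or manually derived), severity from the AHI,
    Cox fit against the non-OSA reference, and per-category Kaplan-Meier
    curves.  Patients with no sleep at some interval are excluded there and
    logged.  The 1-s interval is not analysed by default.
    """
    out: dict[int, FragmentationResult] = {}
    for d in intervals:
        if d not in hypnograms_by_interval:
            raise KeyError(f"no hypnograms supplied for interval {d}")
        ids, durs, cats, excluded = [], [], [], []
        for h in hypnograms_by_interval[d]:
            runs = extract_sleep_runs(h)
            if runs.size == 0:
                logger.warning("patient %s has no sleep at interval %s; excluded",
                               h.patient_id, d)
                excluded.append(h.patient_id)
                continue
            ids.append(h.patient_id)
            durs.append(mean_continuous_sleep(runs))
            cats.append(osa_category(ahi_by_patient[h.patient_id]))
        table = build_survival_table(ids, durs, cats)
        cox = cox_fit(table)
        km = {}
        for cat in CATEGORIES:
            sel = table.frame["category"] == cat
            if sel.any():
                km[cat] = km_estimate(table.frame.loc[sel, "duration_min"],
                                      label=cat)
        out[d] = FragmentationResult(d, table, cox, km, tuple(excluded))
    return out


def plot_km(results: dict[str, KMCurve], ax=None):
    """Step plot of per-category KM curves with confidence bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in results.items():
        ax.step(curve.times, curve.survival, where="post", label=label)
        ax.fill_between(curve.times, curve.ci_lo, curve.ci_hi, alpha=0.2,
                        step="post")
    ax.set_xlabel("mean continuous sleep (min)")
    ax.set_ylabel("fraction of patients")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
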