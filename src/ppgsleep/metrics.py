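"""Per-recording sleep parameters and nonparametric cohort comparisons.

Definitions (all from label counts times the epoch interval ``d``):
TRT = n_labels * d; TST = non-wake labels * d; SE = 100 * TST / TRT;
sleep onset = first non-wake label; WASO = wake time at or after onset up to
the end of the recording (no lights-on annotation exists in this data model,
a documented divergence from the AASM lights-on convention).  Stage
percentages are relative to TST, the wake percentage relative to TRT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hypnogram import Hypnogram

__all__ = [
    "SleepParameters",
    "sleep_parameters",
    "parameter_mae",
    "GroupTestResult",
    "group_compare",
    "normality_test",
]


@dataclass
class SleepParameters:
    patient_id: str
    tst_min: float
    trt_min: float
    se_pct: float
    waso_min: float
    wake_pct_trt: float
    stage_pct_tst: dict[str, float]
    onset_defined: bool
    interval_s: int

    def get(self, name: str) -> float:
        if name in ("tst_min", "trt_min", "se_pct", "waso_min", "wake_pct_trt"):
            return getattr(self, name)
        if name in self.stage_pct_tst:
            return self.stage_pct_tst[name]
        raise KeyError(f"unknown sleep parameter {name!r}")


def sleep_parameters(h: Hypnogram) -> SleepParameters:
    """TST, SE, WASO and stage percentages for one hypnogram.

    An all-wake hypnogram has no sleep onset: ``onset_defined`` is False,
    WASO is 0 and stage percentages are absent (empty dict).
    """
    d_min = h.interval_s / 60.0
    wake = h.wake_mask()
    n = len(h.stages)
    trt = n * d_min
    n_sleep = int((~wake).sum())
    tst = n_sleep * d_min
    se = 100.0 * tst / trt
    if n_sleep == 0:
        return SleepParameters(h.patient_id, 0.0, trt, 0.0, 0.0, 100.0, {},
                               onset_defined=False, interval_s=h.interval_s)
    onset = int(np.argmax(~wake))
    waso = float(wake[onset:].sum()) * d_min
    sleep_labels = [s for s in np.unique(h.stages) if s != "W"]
    pct = {s: 100.0 * float((h.stages == s).sum()) / n_sleep
           for s in sleep_labels}
    return SleepParameters(
        h.patient_id, tst, trt, se, waso,
        wake_pct_trt=100.0 * float(wake.sum()) / n,
        stage_pct_tst=pct, onset_defined=True, interval_s=h.interval_s)


def parameter_mae(ref_set: list[SleepParameters], test_set: list[SleepParameters],
                  name: str) -> float:
    """Mean absolute error of one parameter over patients paired by id."""
    test_by_id = {p.patient_id: p for p in test_set}
    if {p.patient_id for p in ref_set} != set(test_by_id):
        raise ValueError("reference and test sets are not paired by patient")
    errs = [abs(p.get(name) - test_by_id[p.patient_id].get(name))
            for p in ref_set]
    return float(np.mean(errs))


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    pvalue: float
    degenerate: bool = False
    note: str = ""


def group_compare(paired: bool, a, b) -> GroupTestResult:
    """Two-sided nonparametric comparison of two samples.

    Paired samples use the Wilcoxon signed-rank test, independent samples the
    Mann-Whitney U test.  Small samples are tested exactly; larger ones use
    the asymptotic approximation (with continuity correction for Wilcoxon).
    All-tied paired differences leave the test undefined: the result is
    flagged degenerate with p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 observations per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return GroupTestResult("wilcoxon", float("nan"), 1.0,
                                   degenerate=True,
                                   note="all paired differences are zero")
        method = "exact" if len(d) <= 25 and not np.any(d == 0) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return GroupTestResult("wilcoxon", float(res.statistic),
                               float(res.pvalue))
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # ties prevent the exact method
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    return GroupTestResult("mannwhitneyu", float(res.statistic),
                           float(res.pvalue))


def normality_test(x) -> GroupTestResult:
    """Shapiro-Wilk normality check."""
    res = stats.shapiro(np.asarray(x, dtype=float))
    return GroupTestResult("shapiro", float(res.statistic), float(res.pvalue))
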