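"""Run extraction, Cox proportional hazards and Kaplan-Meier machinery."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from ppgsleep import (
    Hypnogram,
    build_survival_table,
    cox_fit,
    extract_sleep_runs,
    fragmentation_analysis,
    km_estimate,
    mean_continuous_sleep,
    osa_category,
)


def _hyp(labels, interval=30, pid="p0"):
    return Hypnogram(np.asarray(labels), interval, 5, patient_id=pid)


class TestOsaCategory:
    @pytest.mark.parametrize("ahi,expected", [
        (0.0, "no"), (4.9, "no"), (5.0, "mild"), (14.99, "mild"),
        (15.0, "moderate"), (29.9, "moderate"), (30.0, "severe"),
        (80.0, "severe"),
    ])
    def test_thresholds(self, ahi, expected):
        assert osa_category(ahi) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            osa_category(-1.0)


def brute_force_runs(labels):
    """Independent run-length encoder over wake/sleep."""
    runs, current = [], 0
    for s in labels:
        if s != "W":
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


class TestSleepRuns:
    def test_hand_enumeration(self):
        runs = extract_sleep_runs(_hyp(["W", "N2", "N2", "R", "W", "N2", "W"]))
        assert np.allclose(runs, [1.5, 0.5])
        assert mean_continuous_sleep(runs) == pytest.approx(1.0)

    def test_all_wake_empty(self):
        assert extract_sleep_runs(_hyp(["W"] * 5)).size == 0
        with pytest.raises(ValueError, match="no sleep"):
            mean_continuous_sleep([])

    def test_all_sleep_single_run(self):
        runs = extract_sleep_runs(_hyp(["N2"] * 7))
        assert np.allclose(runs, [3.5])
        assert mean_continuous_sleep(runs) == 3.5

    def test_exhaustive_against_brute_force(self):
        # every wake/sleep sequence of length <= 10
        for n in range(1, 11):
            for bits in itertools.product([0, 1], repeat=n):
                labels = ["W" if b else "N2" for b in bits]
                expected = np.asarray(brute_force_runs(labels)) * 0.5
                got = extract_sleep_runs(_hyp(labels))
                assert np.allclose(sorted(got), sorted(expected))

    def test_densified_scoring_never_increases_mean(self):
        # wake intrusions invisible to 30-s majority scoring become
        # detectable on the 5-s grid, splitting runs: the 5-s mean cannot
        # exceed the 30-s mean
        rng = np.random.default_rng(0)
        from ppgsleep.simulate import densify_truth

        for seed in range(5):
            dense = np.asarray(["N2"] * 3600)
            wakes = rng.integers(0, 3600 - 20, 8)
            for w in wakes:
                dense[w : w + rng.integers(5, 40)] = "W"
            means = {}
            for d in (30, 5):
                runs = extract_sleep_runs(densify_truth(dense, d))
                means[d] = mean_continuous_sleep(runs)
            assert means[5] <= means[30] + 1e-9


def efron_loglik(beta, durations, covs):
    """Independent Efron partial log-likelihood (all events)."""
    beta = np.atleast_1d(beta)
    eta = covs @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(durations):
        tied = durations == t
        at_risk = durations >= t
        d = int(tied.sum())
        sum_tied = w[tied].sum()
        sum_risk = w[at_risk].sum()
        ll += eta[tied].sum()
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_tied)
    return ll


class TestCoxFit:
    def test_symmetric_groups_give_unit_hazard(self):
        durs = [1.0, 2.0, 3.0, 4.0] * 2
        cats = ["no"] * 4 + ["mild"] * 4
        res = cox_fit(build_survival_table(
            [f"p{i}" for i in range(8)], durs, cats))
        assert res.hr["mild"] == pytest.approx(1.0, abs=1e-6)
        assert res.ci95["mild"][0] < 1.0 < res.ci95["mild"][1]

    def test_toy_table_matches_brute_force_maximizer(self):
        # 6-patient toy table with ties; oracle: numeric maximization of the
        # Efron partial likelihood
        durations = np.asarray([2.0, 3.0, 3.0, 1.0, 2.0, 5.0])
        cats = ["no", "no", "no", "mild", "mild", "mild"]
        covs = np.asarray([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        res = cox_fit(build_survival_table(
            [f"p{i}" for i in range(6)], durations, cats))
        opt = minimize(lambda b: -efron_loglik(b, durations, covs),
                       x0=[0.0], method="BFGS", options={"gtol": 1e-10})
        assert res.beta["mild"] == pytest.approx(float(opt.x[0]), abs=1e-4)
        assert res.loglik == pytest.approx(-float(opt.fun), abs=1e-6)

    def test_three_covariate_table_matches_oracle(self):
        rng = np.random.default_rng(5)
        cats = ["no"] * 6 + ["mild"] * 6 + ["moderate"] * 6 + ["severe"] * 6
        durations = np.round(rng.exponential(10, size=24), 0) + 1
        covs = np.zeros((24, 3))
        for i, c in enumerate(cats):
            if c != "no":
                covs[i, ["mild", "moderate", "severe"].index(c)] = 1.0
        res = cox_fit(build_survival_table(
            [f"p{i}" for i in range(24)], durations, cats))
        opt = minimize(lambda b: -efron_loglik(b, durations, covs),
                       x0=np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10})
        for j, c in enumerate(("mild", "moderate", "severe")):
            assert res.beta[c] == pytest.approx(float(opt.x[j]), abs=1e-4)

    def test_reference_category_not_a_covariate(self):
        res = cox_fit(build_survival_table(
            ["a", "b", "c", "d"], [1.0, 2.0, 3.0, 4.0],
            ["no", "no", "severe", "severe"]))
        assert set(res.hr) == {"severe"}  # reference HR is identically 1

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="2 categories"):
            cox_fit(build_survival_table(["a", "b"], [1.0, 2.0],
                                         ["no", "no"]))


class TestKaplanMeier:
    def test_product_limit_hand_values(self):
        curve = km_estimate([1.0, 2.0, 2.0, 4.0])
        assert curve.survival_at(0.5) == pytest.approx(1.0)
        assert curve.survival_at(1.0) == pytest.approx(0.75)
        assert curve.survival_at(2.0) == pytest.approx(0.25)
        assert curve.survival_at(4.0) == pytest.approx(0.0)

    def test_starts_at_one_non_increasing(self):
        rng = np.random.default_rng(0)
        curve = km_estimate(rng.exponential(5.0, 40))
        assert curve.survival_at(0.0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival.min() >= 0.0

    def test_no_ties_drops_one_over_n(self):
        durations = np.arange(1.0, 11.0)
        curve = km_estimate(durations)
        drops = -np.diff(curve.survival)
        assert np.allclose(drops[drops > 0], 0.1)

    def test_identical_durations_single_drop(self):
        curve = km_estimate([3.0] * 6)
        assert curve.survival_at(2.9) == 1.0
        assert curve.survival_at(3.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestFragmentationAnalysis:
    def _cohort_hypnograms(self, rng, n_per_cat, frag_by_cat):
        """Nights of N2 sleep with category-dependent wake interruptions."""
        hyps, ahi = [], {}
        ahis = {"no": 2.0, "mild": 10.0, "moderate": 20.0, "severe": 40.0}
        pid = 0
        for cat, frag in frag_by_cat.items():
            for _ in range(n_per_cat):
                labels = np.asarray(["N2"] * 240)
                starts = rng.choice(240, size=frag, replace=False)
                labels[starts] = "W"
                h = _hyp(labels, pid=f"p{pid}")
                hyps.append(h)
                ahi[h.patient_id] = ahis[cat]
                pid += 1
        return hyps, ahi

    def test_null_case_all_hazards_near_one(self):
        rng = np.random.default_rng(3)
        frag = {"no": 6, "mild": 6, "moderate": 6, "severe": 6}
        # identical interruption counts but randomized placement
        hyps, ahi = self._cohort_hypnograms(rng, 20, frag)
        res = fragmentation_analysis({30: hyps}, ahi, intervals=(30,))[30]
        for cat in ("mild", "moderate", "severe"):
            assert res.cox.ci95[cat][0] < 1.0 < res.cox.ci95[cat][1]
            assert res.cox.p[cat] > 0.05

    def test_graded_fragmentation_orders_hazards(self):
        rng = np.random.default_rng(4)
        frag = {"no": 2, "mild": 5, "moderate": 12, "severe": 30}
        hyps, ahi = self._cohort_hypnograms(rng, 20, frag)
        res = fragmentation_analysis({30: hyps}, ahi, intervals=(30,))[30]
        assert 1.0 < res.cox.hr["mild"] < res.cox.hr["moderate"] \
            < res.cox.hr["severe"]

    def test_all_wake_patient_excluded(self):
        hyps = [_hyp(["W"] * 240, pid="dead")]
        ahi = {"dead": 2.0}
        rng = np.random.default_rng(5)
        more, more_ahi = self._cohort_hypnograms(
            rng, 5, {"no": 3, "mild": 6, "moderate": 9, "severe": 12})
        ahi.update(more_ahi)
        res = fragmentation_analysis({30: hyps + more}, ahi,
                                     intervals=(30,))[30]
        assert res.excluded == ("dead",)
        assert len(res.table) == 20
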