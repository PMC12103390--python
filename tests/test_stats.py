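"""Statistical layer: exact Wilcoxon, Spearman, cutpoints, KM, log-rank."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from tilquant.model import InsufficientDataError, SurvivalRecord
from tilquant.stats import (
    bh_adjust,
    dichotomized_survival,
    km_estimate,
    log_rank,
    roc_cutpoint,
    spearman,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Two-sided exact p by brute force over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        n_le += w <= w_obs + 1e-12
        n_ge += w >= w_obs - 1e-12
    total = 2**n
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


class TestWilcoxon:
    def test_all_pairs_equal_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and "degenerate" in res.method

    def test_six_positive_differences(self):
        # all six differences positive: exact two-sided p = 2 / 2^6
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        assert res.p_value == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 13))
            d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding makes ties
            if (d == 0).all():
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(
                wilcoxon_enumeration_oracle(d), abs=1e-12
            )

    def test_exact_agrees_with_scipy_without_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 20))
            d = rng.normal(0.5, 1.0, n)  # continuous: no ties, no zeros
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        d = rng.normal(0.4, 1.0, 26)  # just above the exact-enumeration limit
        approx = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert approx.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_pratt_zero_handling(self):
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, -1.0], zero_method="pratt")
        assert res.n == 4  # zeros ranked but not counted


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.estimate == 1.0 and res.p_value == 0.0

    def test_monotone_decreasing_is_minus_one(self):
        res = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.estimate == -1.0

    def test_matches_scipy_including_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x = np.round(rng.normal(size=n), 1)
            y = np.round(0.5 * x + rng.normal(size=n), 1)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            res = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_listwise_missing_removal(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, 8, 10])
        assert res.n == 4 and res.estimate == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2, 3], [1, 2, 3])


def cutpoint_enumeration_oracle(values, outcome):
    """Exhaustive midpoint search replicating the documented tie-breaks.

    Both orientations (high-predicts-event and low-predicts-event) are
    scored, i.e. the absolute Youden J is maximized.
    """
    values = np.asarray(values, float)
    outcome = np.asarray(outcome, int)
    uniq = np.unique(values)
    best = None
    n_pos = (outcome == 1).sum()
    n_neg = (outcome == 0).sum()
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        c = (lo + hi) / 2
        above = values >= c
        sens = (outcome[above] == 1).sum() / n_pos
        spec = (outcome[~above] == 0).sum() / n_neg
        j = abs(sens + spec - 1)
        balance = abs(above.sum() - (~above).sum())
        key = (-j, balance, c)
        if best is None or key < best[0]:
            best = (key, c, j)
    return best[1], best[2]


class TestCutpoint:
    def test_perfect_separation(self):
        res = roc_cutpoint([1, 2, 8, 9], [0, 0, 1, 1])
        assert res.youden_j == pytest.approx(1.0)
        assert 2 < res.cutoff < 8

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_cutpoint([1, 2, 3], [1, 1, 1])

    def test_constant_feature_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_cutpoint([5, 5, 5, 5], [0, 1, 0, 1])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 21))
            values = np.round(rng.normal(size=n), 1)
            outcome = (rng.random(n) < 0.5).astype(int)
            if outcome.min() == outcome.max() or len(np.unique(values)) < 2:
                continue
            res = roc_cutpoint(values, outcome)
            cut, j = cutpoint_enumeration_oracle(values, outcome)
            assert res.cutoff == pytest.approx(cut, abs=1e-12)
            assert res.youden_j == pytest.approx(j, abs=1e-12)

    def test_independent_outcome_j_near_zero(self, rng):
        js = []
        for _ in range(50):
            values = rng.normal(size=400)
            outcome = (rng.random(400) < 0.5).astype(int)
            js.append(roc_cutpoint(values, outcome).youden_j)
        # optimized J is biased upward but shrinks toward 0 at this n
        assert 0 <= np.mean(js) < 0.15


def _records(times, events):
    return [
        SurvivalRecord(f"P{i:03d}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_ten_uncensored_deaths_median_five(self):
        km = km_estimate(_records(range(1, 11), [1] * 10))
        assert km.median == 5.0  # smallest t with S(t) <= 0.5

    def test_all_censored_median_not_reached(self):
        km = km_estimate(_records([5, 10, 15], [0, 0, 0]))
        assert not km.median_reached and math.isinf(km.median)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10.0, 200)
        km = km_estimate(_records(times, np.ones(200)))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(12.0, 150)
        events = (rng.random(150) < 0.7).astype(int)
        km = km_estimate(_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.survival, ref, atol=1e-10)

    def test_deaths_precede_censorings_at_ties(self):
        # death and censoring at t=5: both at risk at 5, one death
        km = km_estimate(_records([5.0, 5.0, 8.0], [1, 0, 1]))
        assert km.survival_at(5.0) == pytest.approx(2 / 3)


class TestLogRank:
    def test_identical_groups_p_one(self):
        g = _records([1, 2, 3, 4], [1, 1, 1, 1])
        res = log_rank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # group A deaths at 1, 2; group B death at 3; no censoring.
        # t=1: n=(2,1), d=1 in A: E_A=2/3, V=2*1/9=2/9
        # t=2: n=(1,1), d=1 in A: E_A=1/2, V=1/4
        # t=3: n=(0,1), d=1 in B: E_A=0,  V=0
        # O_A-E_A = 2-7/6 = 5/6; chi2 = (5/6)^2 / (2/9+1/4) = 25/17
        res = log_rank(
            [_records([1, 2], [1, 1]), _records([3], [1])]
        )
        assert res.statistic == pytest.approx(25 / 17, rel=1e-12)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t1 = rng.exponential(10, 80)
        t2 = rng.exponential(14, 70)
        e1 = (rng.random(80) < 0.8).astype(int)
        e2 = (rng.random(70) < 0.8).astype(int)
        res = log_rank([_records(t1, e1), _records(t2, e2)])
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_three_group_agrees_with_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = [rng.exponential(m, 50) for m in (8, 10, 14)]
        events = [(rng.random(50) < 0.8).astype(int) for _ in range(3)]
        res = log_rank([_records(t, e) for t, e in zip(times, events)])
        df = np.concatenate(times)
        ev = np.concatenate(events)
        grp = np.repeat([0, 1, 2], 50)
        ref = multivariate_logrank_test(df, grp, ev)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_invariant_to_time_scaling(self, rng):
        t1 = rng.exponential(10, 40)
        t2 = rng.exponential(20, 40)
        e = np.ones(40, dtype=int)
        a = log_rank([_records(t1, e), _records(t2, e)])
        b = log_rank([_records(t1 * 7.3, e), _records(t2 * 7.3, e)])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            log_rank([_records([1], [1]), []])


class TestDichotomized:
    def test_constant_feature_flagged(self):
        recs = _records([1, 2, 3, 4], [1, 1, 0, 1])
        res = dichotomized_survival(
            {r.patient_id: 5.0 for r in recs}, recs
        )
        assert res.degenerate and res.logrank is None

    def test_separating_feature_recovers_groups(self, rng):
        n = 60
        raw = np.r_[rng.exponential(5, n // 2), rng.exponential(50, n // 2)]
        censor = 60.0  # administrative censoring keeps both outcome classes
        recs = _records(np.minimum(raw, censor), raw <= censor)
        feature = {
            r.patient_id: (0.0 if i < n // 2 else 1.0) + rng.normal(0, 0.01)
            for i, r in enumerate(recs)
        }
        res = dichotomized_survival(feature, recs)
        assert not res.degenerate
        assert res.km_high.median > res.km_low.median
        assert res.logrank.p_value < 0.001

    def test_permutation_p_larger_than_raw_under_null(self, rng):
        # with an uninformative feature the optimized raw p is optimistic;
        # the permutation calibration must not be smaller on average
        n = 40
        raw = rng.exponential(10, n)
        recs = _records(np.minimum(raw, 25.0), raw <= 25.0)
        feature = {r.patient_id: float(v) for r, v in zip(recs, rng.normal(size=n))}
        res = dichotomized_survival(
            feature, recs, n_permutations=200, rng=np.random.default_rng(5)
        )
        assert res.permutation_p is not None
        assert res.permutation_p >= res.logrank.p_value * 0.5


def test_bh_adjustment_monotone():
    p = [0.001, 0.02, 0.04, 0.5]
    adj = bh_adjust(p)
    assert (np.diff(adj) >= 0).all()
    assert adj[0] == pytest.approx(0.004)
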