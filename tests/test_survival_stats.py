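"""Survival machinery against hand calculations and lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest

from mbrisk.exceptions import UndefinedConcordanceError
from mbrisk.survival_stats import (
    compare_covariate,
    compare_groups,
    concordance_index,
    cox_hazard_ratio,
    kaplan_meier,
    logrank_test,
)


def _df(times, events):
    return pd.DataFrame({"time_days": times, "event": events})


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = kaplan_meier(_df([1, 2, 3], [1, 1, 1]))
        assert np.allclose(km.survival_prob, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_flat_curve(self):
        km = kaplan_meier(_df([1, 2, 3], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_censoring_shrinks_risk_set(self):
        km = kaplan_meier(_df([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        km = kaplan_meier(_df(t, np.ones(40, int)))
        for q in (np.percentile(t, 30), np.percentile(t, 70)):
            emp = np.mean(t > q)
            assert km.survival_at(q) == pytest.approx(emp)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        km = kaplan_meier(_df(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for tt in km.event_times:
            assert km.survival_at(tt) == pytest.approx(
                float(kmf.predict(tt)), abs=1e-9)


class TestLogRank:
    def test_identical_groups_yield_null(self):
        df = _df([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        chi2, p = logrank_test(df, [0, 0, 0, 1, 1, 1])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_hand_oe_table(self):
        """Group A fails at 1,2,3; group B at 4,5,6: accumulate O-E and the
        hypergeometric variance over the six risk sets by hand."""
        times = np.array([1, 2, 3, 4, 5, 6], float)
        groups = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in times:
            at_risk = times >= t
            n, n0 = at_risk.sum(), (at_risk & (groups == 0)).sum()
            o_minus_e += (1.0 if groups[times == t][0] == 0 else 0.0) - n0 / n
            if n > 1:
                var += (n0 / n) * (1 - n0 / n)  # d=1 each time
        expected_chi2 = o_minus_e**2 / var
        chi2, p = logrank_test(_df(times, np.ones(6, int)), groups)
        assert chi2 == pytest.approx(expected_chi2)

    def test_no_events_returns_p_one(self):
        assert logrank_test(_df([1, 2], [0, 0]), [0, 1]) == (0.0, 1.0)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        g = rng.integers(0, 2, 50)
        t[g == 1] *= 0.5
        chi2, p = logrank_test(_df(t, e), g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def _breslow_loglik(beta, times, events, x):
    """Independent Breslow partial log-likelihood for the grid oracle."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d_idx = (times == t) & (events == 1)
        ll += beta * x[d_idx].sum() - d_idx.sum() * np.log(
            np.exp(beta * x[at_risk]).sum())
    return ll


class TestCoxHazardRatio:
    def test_identical_groups_give_unit_hazard_ratio(self):
        df = _df([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        hr, (lo, hi) = cox_hazard_ratio(df, [0, 0, 0, 1, 1, 1])
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo <= hr <= hi

    def test_six_subject_toy_matches_grid_search(self):
        times = np.array([2.0, 4.0, 5.0, 1.0, 3.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        grid = np.linspace(-4, 4, 16001)
        lls = [_breslow_loglik(b, times, events, x) for b in grid]
        beta_oracle = grid[int(np.argmax(lls))]
        hr, _ = cox_hazard_ratio(_df(times, events), x)
        assert np.log(hr) == pytest.approx(beta_oracle, abs=1e-3)

    def test_swapping_groups_inverts_hazard_ratio(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 30)
        e = np.ones(30, int)
        g = rng.integers(0, 2, 30)
        hr_a, _ = cox_hazard_ratio(_df(t, e), g)
        hr_b, _ = cox_hazard_ratio(_df(t, e), 1 - g)
        assert hr_a * hr_b == pytest.approx(1.0, rel=1e-8)

    def test_matches_lifelines_estimate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        g = rng.integers(0, 2, 50)
        t = rng.exponential(10, 50) * np.exp(-0.7 * g)
        e = (rng.uniform(size=50) > 0.25).astype(int)
        hr, _ = cox_hazard_ratio(_df(t, e), g)
        cph = CoxPHFitter().fit(pd.DataFrame({"T": t, "E": e, "g": g}), "T", "E")
        assert np.log(hr) == pytest.approx(cph.params_.iloc[0], abs=1e-4)


class TestConcordance:
    def test_perfect_ranking(self):
        df = _df([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert concordance_index([-1, -2, -3, -4, -5], df) == 1.0

    def test_all_tied_scores_give_half(self):
        df = _df([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert concordance_index([2, 2, 2, 2, 2], df) == 0.5

    def test_censored_pair_enumeration(self):
        """5 subjects, one censored: enumerate permissible pairs by hand."""
        times = [2.0, 4.0, 3.0, 5.0, 1.0]
        events = [1, 1, 0, 1, 1]
        scores = [3.0, 1.0, 2.0, 0.5, 4.0]
        num = den = 0.0
        for i in range(5):
            if events[i] != 1:
                continue
            for j in range(5):
                if i == j:
                    continue
                if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                    den += 1
                    if scores[i] > scores[j]:
                        num += 1
                    elif scores[i] == scores[j]:
                        num += 0.5
        assert concordance_index(scores, _df(times, events)) == num / den

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        s = rng.standard_normal(40)
        df = _df(t, e)
        assert concordance_index(s, df) == concordance_index(np.exp(s) + 3, df)

    def test_no_permissible_pairs_raises(self):
        with pytest.raises(UndefinedConcordanceError):
            concordance_index([1, 2], _df([1, 2], [0, 0]))

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index as ll_ci

        rng = np.random.default_rng(6)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        s = rng.standard_normal(50)
        # lifelines counts concordance of predicted *survival* times
        assert concordance_index(s, _df(t, e)) == pytest.approx(
            1.0 - ll_ci(t, s, e))


class TestCompareCovariate:
    def test_identical_groups_p_one(self):
        assert compare_covariate([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == \
            pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        p = compare_covariate([0, 0, 0, 0, 10, 10.1, 9.9, 10],
                              [0, 0, 0, 0, 1, 1, 1, 1])
        assert p < 1e-3

    def test_matches_welch_formula(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8])
        from scipy import stats

        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        expected = 2 * stats.t.sf(abs(tstat), dof)
        got = compare_covariate(np.concatenate([a, b]),
                                [0] * len(a) + [1] * len(b))
        assert got == pytest.approx(expected, rel=1e-9)


class TestPropertyInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        times=st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1,
                       max_size=25),
        events=st.data(),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_km_curve_is_monotone_step_function_in_unit_range(self, times,
                                                              events):
        e = events.draw(self.st.lists(self.st.integers(0, 1),
                                      min_size=len(times),
                                      max_size=len(times)))
        km = kaplan_meier(_df(times, e))
        assert np.all(np.diff(km.survival_prob) <= 1e-12)
        assert np.all((km.survival_prob >= 0) & (km.survival_prob <= 1))
        assert km.survival_at(0.0) == 1.0

    @given(shift=st.floats(min_value=-5, max_value=5),
           scale=st.floats(min_value=0.01, max_value=10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_concordance_invariant_under_increasing_affine_maps(self, shift,
                                                                scale):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        s = rng.standard_normal(30)
        df = _df(t, e)
        assert concordance_index(s, df) == pytest.approx(
            concordance_index(scale * s + shift, df))


class TestCompareGroups:
    def test_bundles_all_metrics(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 2, 40)
        t = rng.exponential(10, 40) * np.exp(-0.8 * g)
        cmp_ = compare_groups(_df(t, np.ones(40, int)), g)
        assert cmp_.n_low + cmp_.n_high == 40
        assert cmp_.hr_ci95[0] <= cmp_.hazard_ratio <= cmp_.hr_ci95[1]
        assert 0 <= cmp_.c_index <= 1
        assert 0 < cmp_.p_value <= 1
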