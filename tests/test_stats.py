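import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tugpcm.stats import (
    ComparisonResult,
    DisabilityIndicators,
    chi_square_2x2,
    classify_disability,
    cohens_d,
    cohens_d_from_summary,
    compare_pc_scores,
    mann_whitney_u,
    normality_gate,
    pooled_t_from_summary,
)


def make_indicators(**over):
    base = dict(
        self_reported_health="good", sex="male", handgrip_kg=40.0,
        one_leg_stance_s=60.0, barthel=20, lawton=23,
    )
    base.update(over)
    return DisabilityIndicators(**base)


class TestClassification:
    def test_two_indicators_is_disability(self):
        ind = make_indicators(sex="female", handgrip_kg=15.0, one_leg_stance_s=8.0)
        assert classify_disability(ind) == ("D", 2)

    def test_healthy_profile_is_nd(self):
        assert classify_disability(make_indicators()) == ("ND", 0)

    def test_single_indicator_stays_nd(self):
        ind = make_indicators(handgrip_kg=26.0)
        assert classify_disability(ind) == ("ND", 1)

    @given(
        grip=st.floats(5, 50), stance=st.floats(0, 60),
        barthel=st.integers(0, 20), lawton=st.integers(0, 23),
        srh=st.sampled_from(["good", "poor"]),
        sex=st.sampled_from(["male", "female"]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_worsening_an_indicator_never_flips_d_to_nd(
        self, grip, stance, barthel, lawton, srh, sex
    ):
        ind = make_indicators(
            sex=sex, handgrip_kg=grip, one_leg_stance_s=stance,
            barthel=barthel, lawton=lawton, self_reported_health=srh,
        )
        label, count = classify_disability(ind)
        worse = make_indicators(
            sex=sex, handgrip_kg=min(grip, 10.0), one_leg_stance_s=stance,
            barthel=barthel, lawton=lawton, self_reported_health=srh,
        )
        wl, wc = classify_disability(worse)
        assert wc >= count
        if label == "D":
            assert wl == "D"


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, continuity, expected",
        [
            ((2, 33, 11, 14), False, 12.595),  # polypharmacy
            ((8, 27, 21, 4), False, 21.832),  # self-reported health
            ((19, 16, 19, 6), False, 2.961),  # sex distribution
            ((11, 24, 11, 14), True, 0.525),  # fall history, Yates-corrected
        ],
    )
    def test_published_group_counts_reproduce_printed_statistics(
        self, table, continuity, expected
    ):
        chi2, p = chi_square_2x2(*table, continuity=continuity)
        assert chi2 == pytest.approx(expected, abs=5e-4)
        assert 0 <= p <= 1

    def test_proportional_table_gives_zero(self):
        chi2, p = chi_square_2x2(10, 20, 5, 10)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariance_to_transposition_and_double_swap(self, table):
        a, b, c, d = table
        base = chi_square_2x2(a, b, c, d)[0]
        assert chi_square_2x2(a, c, b, d)[0] == pytest.approx(base, rel=1e-12)
        assert chi_square_2x2(d, c, b, a)[0] == pytest.approx(base, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2(0, 0, 5, 5)


class TestPooledT:
    def test_published_bmi_summaries_reproduce_printed_t(self):
        t, df, p = pooled_t_from_summary(25.22, 3.08, 35, 26.02, 2.66, 25)
        assert t == pytest.approx(-1.049, abs=5e-4)
        assert df == 58

    def test_equal_groups_give_t_zero(self):
        t, df, p = pooled_t_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy_from_raw_samples(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1.3, 22)
        t, df, p = pooled_t_from_summary(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
        )
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pooled_t_from_summary(1, 0, 5, 2, 0, 5)


def _mwu_exact_oracle(x, y):
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestMannWhitney:
    def test_identical_samples_give_half_the_pairs(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 8.0  # n1*n2/2

    def test_complete_separation_gives_zero(self):
        u, p = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u == 0.0

    def test_exact_p_matches_full_enumeration_for_all_rank_splits(self):
        values = np.arange(1.0, 9.0)
        for idx in itertools.combinations(range(8), 4):
            x = values[list(idx)]
            y = np.delete(values, list(idx))
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(_mwu_exact_oracle(x, y), abs=1e-12)

    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=15),
        st.lists(st.integers(0, 30), min_size=2, max_size=15),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_u_plus_complement_is_n1_times_n2(self, xs, ys):
        u, _ = mann_whitney_u(xs, ys)
        assert 0 <= u <= len(xs) * len(ys) / 2


class TestCohensD:
    def test_equal_means_give_zero_with_symmetric_ci(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        d, lo, hi = cohens_d(x, x.copy())
        assert d == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_one_sd_shift_recovers_d_of_one_at_large_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 20000)
        y = rng.normal(0.0, 1.0, 20000)
        d, lo, hi = cohens_d(x, y)
        assert d == pytest.approx(1.0, abs=0.05)
        assert lo < 1.0 < hi

    def test_summary_route_matches_raw_route(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 35), rng.normal(0.5, 1, 25)
        raw = cohens_d(x, y)
        summ = cohens_d_from_summary(
            x.mean(), x.std(ddof=1), 35, y.mean(), y.std(ddof=1), 25
        )
        assert raw == pytest.approx(summ, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d([1, 1, 1], [1, 1, 1])


class TestNormalityGate:
    def test_two_normal_samples_usually_parametric(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            route = normality_gate(rng.normal(0, 1, 35), rng.normal(0, 1, 50))
            hits += route == "parametric"
        assert hits >= 16

    def test_exponential_sample_usually_nonparametric(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            route = normality_gate(rng.normal(0, 1, 35), rng.exponential(1, 50))
            hits += route == "nonparametric"
        assert hits >= 18

    def test_tiny_samples_still_return_a_decision(self):
        route = normality_gate([0.1, 0.5, 0.9], [0.2, 0.4, 0.8])
        assert route in ("parametric", "nonparametric")


class TestComparePCScores:
    def test_identical_groups_have_zero_effect(self, feature_table):
        import pandas as pd

        rng = np.random.default_rng(3)
        scores = pd.DataFrame(
            {"pc1": np.tile(rng.normal(size=10), 2)},
            index=[f"s{i}" for i in range(20)],
        )
        labels = pd.Series(
            ["ND"] * 10 + ["D"] * 10, index=scores.index
        )
        scores.iloc[10:, 0] = scores.iloc[:10, 0].to_numpy()
        out = compare_pc_scores(scores, labels)
        assert out.loc["pc1", "cohens_d"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_label_is_an_error(self):
        import pandas as pd

        scores = pd.DataFrame({"pc1": [1.0, 2.0]}, index=["a", "b"])
        labels = pd.Series({"a": "ND"})
        with pytest.raises(ValueError, match="no group label"):
            compare_pc_scores(scores, labels)

    def test_result_invariants_hold(self):
        res = ComparisonResult(
            name="x", statistic_name="U", statistic_value=10.0, p_value=0.5,
            effect_size_d=0.2, d_ci_low=-0.1, d_ci_high=0.5,
            n_group1=5, n_group2=5,
        )
        assert res.d_ci_low <= res.effect_size_d <= res.d_ci_high
        with pytest.raises(ValueError):
            ComparisonResult(
                name="x", statistic_name="U", statistic_value=1.0, p_value=1.5,
                effect_size_d=0.0, d_ci_low=0.0, d_ci_high=0.0,
                n_group1=2, n_group2=2,
            )
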