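import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulmhet.core import Metric
from pulmhet.heterogeneity import (
    BipartitionScheme,
    TooFewLesionsError,
    TVariant,
    assess_heterogeneity,
    bipartitions,
    count_balanced_bipartitions,
    min_combination_p,
    overall_verdict,
    two_sample_p,
)
from conftest import make_series


def brute_force_min_p(rates, equal_var=True):
    """Independent oracle: enumerate every balanced split with itertools and
    take the minimum scipy two-sample p."""
    x = list(rates)
    n = len(x)
    k = n // 2
    best = math.inf
    seen = set()
    for comb in itertools.combinations(range(n), k):
        grp = frozenset(comb)
        if n % 2 == 0 and 0 not in grp:
            grp = frozenset(range(n)) - grp
        if grp in seen:
            continue
        seen.add(grp)
        a = [x[i] for i in grp]
        b = [x[i] for i in range(n) if i not in grp]
        best = min(best, stats.ttest_ind(a, b, equal_var=equal_var)[1])
    return best


class TestCounting:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (31, 300_540_195),  # C(31,15)
            (4, 3),             # {12|34},{13|24},{14|23} by enumeration
            (5, 10),            # C(5,2)
            (6, 10),            # C(6,3)/2
            (8, 35),
        ],
    )
    def test_counts(self, n, expected):
        assert count_balanced_bipartitions(n) == expected

    def test_too_few_lesions(self):
        with pytest.raises(TooFewLesionsError):
            count_balanced_bipartitions(3)


class TestBipartitions:
    def test_n4_exhaustive_listing(self):
        parts = bipartitions(4).evaluated_partitions
        assert set(parts) == {
            ((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))
        }

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8, 9])
    def test_full_enumeration_is_exact_and_disjoint(self, n):
        scheme = bipartitions(n)
        assert len(scheme.evaluated_partitions) == count_balanced_bipartitions(n)
        seen = set()
        for a, b in scheme.evaluated_partitions:
            assert sorted(a + b) == list(range(n))
            assert len(a) == n // 2
            key = frozenset(a) if n % 2 else min(frozenset(a), frozenset(b), key=sorted)
            assert key not in seen
            seen.add(key)

    def test_capped_sampling_is_distinct_and_reproducible(self):
        s1 = bipartitions(8, cap=5, seed=1)
        s2 = bipartitions(8, cap=5, seed=1)
        assert len(s1.evaluated_partitions) == 5
        assert len({frozenset(a) for a, _ in s1.evaluated_partitions}) == 5
        assert s1.evaluated_partitions == s2.evaluated_partitions
        assert s1.sampled and s1.sampling_seed == 1

    def test_large_n_sampling_respects_cap_and_dedupes_complements(self):
        scheme = bipartitions(20, cap=4000, seed=3)
        assert len(scheme.evaluated_partitions) == 4000
        keys = {frozenset(a) for a, _ in scheme.evaluated_partitions}
        comps = {frozenset(b) for _, b in scheme.evaluated_partitions}
        assert len(keys) == 4000 and not keys & comps


class TestTwoSampleP:
    def test_identical_samples_give_p_one(self):
        assert two_sample_p([1, 2, 3], [1, 2, 3]) == 1.0

    def test_zero_variance_separated_groups_give_p_zero(self):
        assert two_sample_p([0, 0], [10, 10]) == 0.0

    def test_zero_variance_equal_groups_give_p_one(self):
        assert two_sample_p([5, 5, 5], [5, 5]) == 1.0

    def test_pooled_matches_hand_computed_t(self):
        # pooled t = -1.095, df = 6
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        sp2 = (3 * np.var(a, ddof=1) + 3 * np.var(b, ddof=1)) / 6
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert t == pytest.approx(-1.095, abs=5e-4)
        assert two_sample_p(a, b) == pytest.approx(2 * stats.t.sf(abs(t), 6), rel=1e-12)

    @pytest.mark.parametrize("variant, equal_var", [(TVariant.POOLED, True), (TVariant.WELCH, False)])
    def test_matches_scipy_on_random_data(self, variant, equal_var):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 2, rng.integers(2, 8))
            expect = stats.ttest_ind(a, b, equal_var=equal_var)[1]
            assert two_sample_p(a, b, variant) == pytest.approx(expect, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(TooFewLesionsError):
            two_sample_p([1], [2, 3])


class TestMinCombinationP:
    def test_constant_rates_give_p_one(self):
        assert min_combination_p([7.0] * 6)[0] == 1.0

    def test_perfectly_separated_rates_give_p_zero(self):
        p, argmin, degen = min_combination_p([0, 0, 0, 100, 100, 100])
        assert p == 0.0 and degen
        assert set(argmin[0]) in ({0, 1, 2}, {3, 4, 5})

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8, 9, 10])
    def test_equals_exhaustive_oracle(self, n):
        rng = np.random.default_rng(n)
        rates = rng.normal(10, 20, n)
        p, _, _ = min_combination_p(rates, cap=10**6)
        assert p == pytest.approx(brute_force_min_p(rates), rel=1e-10)

    def test_welch_variant_equals_welch_oracle(self):
        rng = np.random.default_rng(42)
        rates = rng.normal(0, 15, 8)
        p, _, _ = min_combination_p(rates, cap=100, variant=TVariant.WELCH)
        assert p == pytest.approx(brute_force_min_p(rates, equal_var=False), rel=1e-10)

    def test_linear_ramp_matches_oracle(self):
        rates = [1, 2, 3, 4, 5, 6, 7, 8]
        p, _, _ = min_combination_p(rates, cap=35)
        assert p == pytest.approx(brute_force_min_p(rates), rel=1e-10)

    def test_sampled_minimum_bounded_below_by_full_minimum(self):
        rng = np.random.default_rng(5)
        rates = rng.normal(0, 10, 12)
        full, _, _ = min_combination_p(rates, cap=10**6)
        for seed in range(5):
            sub, _, _ = min_combination_p(rates, cap=50, seed=seed)
            assert sub >= full - 1e-15

    @given(perm_seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance_of_full_enumeration(self, perm_seed):
        rng = np.random.default_rng(17)
        rates = rng.normal(0, 10, 8)
        shuffled = np.random.default_rng(perm_seed).permutation(rates)
        p1, _, _ = min_combination_p(rates, cap=100)
        p2, _, _ = min_combination_p(shuffled, cap=100)
        assert p1 == pytest.approx(p2, rel=1e-10)


class TestAssessHeterogeneity:
    def test_requires_four_nodules(self):
        s = make_series([(1.0, 1.1), (1.0, 1.2), (1.0, 1.0)])
        with pytest.raises(TooFewLesionsError):
            assess_heterogeneity(s)

    def test_two_growth_populations_detected(self):
        s = make_series(
            [(1.0, 1.01), (1.0, 1.02), (1.0, 0.99), (1.0, 1.0),
             (1.0, 1.52), (1.0, 1.49), (1.0, 1.51), (1.0, 1.50)]
        )
        res = assess_heterogeneity(s, seed=0)
        assert res.heterogeneous
        assert res.min_min_p == min(res.min_p_diameter, res.min_p_volume)

    def test_homogeneous_zero_growth_not_flagged(self):
        s = make_series([(1.0, 1.0)] * 5 + [(2.0, 2.0)] * 3)
        res = assess_heterogeneity(s, seed=0)
        assert res.min_p_diameter == 1.0 and not res.heterogeneous

    def test_shared_scheme_across_metrics(self):
        s = make_series([(1.0, 1.0 + 0.05 * i) for i in range(6)])
        res = assess_heterogeneity(s, seed=1)
        # exact cube law: argmin split should coincide across metrics
        assert res.argmin_partition_diameter is not None


class TestOverallVerdict:
    @pytest.mark.parametrize(
        "p_d, p_v, expected_min, expected_het",
        [
            (0.0324, 0.1955, 0.0324, True),    # a heterogeneous patient
            (0.2815, 0.3005, 0.2815, False),   # a homogeneous one
            (0.0305, 0.0283, 0.0283, True),
        ],
    )
    def test_rule(self, p_d, p_v, expected_min, expected_het):
        mm, het = overall_verdict(p_d, p_v)
        assert mm == expected_min and het is expected_het

    def test_published_pvalue_table_gives_six_heterogeneous(self, heterogeneity_table):
        verdicts = [
            overall_verdict(r.min_p_diameter, r.min_p_volume)
            for r in heterogeneity_table.itertuples()
        ]
        assert [v for _, v in verdicts].count(True) == 6
        flagged = [r.patient_id for r, (_, v) in
                   zip(heterogeneity_table.itertuples(), verdicts) if v]
        assert flagged == [5, 6, 7, 8, 9, 10]
        for r, (mm, v) in zip(heterogeneity_table.itertuples(), verdicts):
            assert mm == r.min_min_p and v == r.heterogeneous
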