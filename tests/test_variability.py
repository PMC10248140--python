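"""MAD, bootstrap SE, permutation inference, BH adjustment, rank tests."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ymaze import (
    bh_adjust,
    bootstrap_mad_se,
    compare_groups,
    compute_mad,
    group_variability,
    permutation_test_mad,
    rank_tests,
)
def brute_force_mad_permutation_p(a, b, tie_rule="ge"):
    """Independent oracle: enumerate every label assignment by bitmask."""
    pool = list(a) + list(b)
    n, na = len(pool), len(a)

    def mad(v):
        v = sorted(v)
        m = len(v)
        med = (v[m // 2] if m % 2 else (v[m // 2 - 1] + v[m // 2]) / 2)
        d = sorted(abs(x - med) for x in v)
        return d[m // 2] if m % 2 else (d[m // 2 - 1] + d[m // 2]) / 2

    observed = abs(mad(a) - mad(b))
    count = total = 0
    for combo in itertools.combinations(range(n), na):
        in_a = set(combo)
        ga = [pool[i] for i in range(n) if i in in_a]
        gb = [pool[i] for i in range(n) if i not in in_a]
        s = abs(mad(ga) - mad(gb))
        hit = s >= observed - 1e-12 if tie_rule == "ge" else s > observed + 1e-12
        count += hit
        total += 1
    return count / total


class TestComputeMad:
    def test_constant_data(self):
        assert compute_mad([0.5, 0.5, 0.5]) == 0.0

    def test_hand_computed_example(self):
        # median 0.5; deviations 0.3, 0.1, 0.1, 0.3 -> median 0.2
        assert compute_mad([0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.2)

    def test_no_consistency_scaling(self):
        # the normal-consistency factor 1.4826 must NOT be applied
        rng = np.random.default_rng(0)
        v = rng.normal(size=1000)
        assert compute_mad(v) == pytest.approx(
            stats.median_abs_deviation(v, scale=1.0)
        )

    def test_reflection_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=101)
        assert compute_mad(v) == pytest.approx(compute_mad(1 - v), abs=1e-15)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            compute_mad([])

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50),
        st.floats(-1e3, 1e3),
    )
    def test_translation_invariance(self, values, c):
        v = np.asarray(values)
        assert compute_mad(v + c) == pytest.approx(compute_mad(v), abs=1e-9)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50),
        st.floats(-100, 100),
    )
    def test_absolute_homogeneity(self, values, c):
        v = np.asarray(values)
        assert compute_mad(c * v) == pytest.approx(
            abs(c) * compute_mad(v), rel=1e-9, abs=1e-9
        )

    def test_uniform_sample_converges_to_quartile_value(self):
        # |U - 1/2| is uniform on [0, 1/2]; its median is 1/4
        v = np.random.default_rng(2).uniform(size=200_000)
        assert compute_mad(v) == pytest.approx(0.25, abs=0.005)


class TestBootstrapSe:
    def test_constant_data_has_zero_se(self):
        assert bootstrap_mad_se([0.4] * 20, seed=0) == 0.0

    def test_matches_independently_coded_resampler(self):
        v = np.array([0.1, 0.3, 0.35, 0.5, 0.62, 0.7, 0.9])
        got = bootstrap_mad_se(v, n_boot=500, seed=123)
        # oracle: plain-python loop drawing one index row at a time from the
        # same bit stream
        rng = np.random.default_rng(123)
        mads = []
        for _ in range(500):
            idx = rng.integers(0, len(v), len(v))
            mads.append(compute_mad(v[idx]))
        assert got == pytest.approx(np.std(mads, ddof=1))

    def test_se_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        ses = {}
        for n in (50, 500):
            reps = [
                bootstrap_mad_se(rng.beta(8, 8, n), n_boot=300, seed=i)
                for i in range(8)
            ]
            ses[n] = np.mean(reps)
        assert ses[500] < ses[50]

    def test_single_observation_is_an_error(self):
        with pytest.raises(ValueError):
            bootstrap_mad_se([0.5], seed=0)


class TestPermutationTest:
    def test_degenerate_constant_groups_give_p_one(self):
        r = permutation_test_mad([0.5] * 5, [0.5] * 5, n_perm=99, seed=0)
        assert r.observed_abs_diff == 0.0
        assert r.p_raw == 1.0

    def test_exact_enumeration_matches_independent_oracle(self):
        a, b = [0.5, 0.5, 0.5], [0.1, 0.5, 0.9]
        r = permutation_test_mad(a, b, method="exact")
        assert r.n_perm == 20  # C(6, 3) label assignments
        assert r.p_raw == brute_force_mad_permutation_p(a, b)

    def test_strict_tie_rule_counts_fewer_exceedances(self):
        a, b = [0.5, 0.5, 0.5], [0.1, 0.5, 0.9]
        ge = permutation_test_mad(a, b, method="exact", tie_rule="ge")
        gt = permutation_test_mad(a, b, method="exact", tie_rule="greater")
        assert gt.p_raw <= ge.p_raw
        assert gt.p_raw == brute_force_mad_permutation_p(a, b, tie_rule="greater")

    def test_bit_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.beta(8, 8, 40), rng.beta(3, 3, 35)
        r1 = permutation_test_mad(a, b, n_perm=2000, seed=99)
        r2 = permutation_test_mad(a, b, n_perm=2000, seed=99)
        assert (r1.n_exceed, r1.p_raw) == (r2.n_exceed, r2.p_raw)

    def test_plus_one_correction_mode(self):
        rng = np.random.default_rng(5)
        a, b = rng.beta(8, 8, 30), rng.beta(8, 8, 30)
        r = permutation_test_mad(a, b, n_perm=99, seed=0, plus_one=True)
        assert r.p_raw == (r.n_exceed + 1) / (r.n_perm + 1)
        assert r.p_raw > 0

    def test_tiny_groups_are_an_error(self):
        with pytest.raises(ValueError, match="at least two"):
            permutation_test_mad([0.5], [0.1, 0.9], n_perm=9, seed=0)

    def test_power_exceeds_size_for_unequal_concentrations(self):
        # dispersion difference (concentration 6 vs 16) must be detected more
        # often than the nominal false-positive rate under equal models
        rng = np.random.default_rng(6)
        null_rej = alt_rej = 0
        n_rep = 60
        for _ in range(n_rep):
            a = rng.beta(8, 8, 80)
            null_rej += permutation_test_mad(a, rng.beta(8, 8, 80), 199, rng).p_raw <= 0.05
            alt_rej += permutation_test_mad(rng.beta(3, 3, 80), rng.beta(8, 8, 80), 199, rng).p_raw <= 0.05
        assert alt_rej > null_rej


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # m=4: candidates 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 -> all 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_inputs_map_to_themselves(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_never_below_raw_and_capped_at_one(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_monotone_in_the_order_statistics(self, p):
        order = np.argsort(p)
        adj = np.asarray(bh_adjust(p))[order]
        assert np.all(np.diff(adj) >= -1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_hand_coded_step_up_oracle(self, p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        adj = [None] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert bh_adjust(p) == pytest.approx(adj)


class TestGroupLevelApi:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "yes:none": rng.beta(4, 4, 60),
            "no:none": rng.beta(8, 8, 60),
            "yes:amw": rng.beta(6, 6, 60),
        }

    def test_group_variability_reports_all_groups(self):
        gv = group_variability(self._cohort(), n_boot=200, seed=1)
        assert [g.group for g in gv] == ["no:none", "yes:amw", "yes:none"]
        assert all(g.mad > 0 and g.bootstrap_se > 0 for g in gv)

    def test_compare_groups_adjusts_over_the_family(self):
        groups = self._cohort()
        pairs = [("yes:none", "no:none"), ("yes:amw", "no:none")]
        res = compare_groups(groups, pairs, n_perm=499, seed=2)
        assert len(res) == 2
        for r in res:
            assert r.p_adjusted >= r.p_raw - 1e-12
            assert 0 <= r.n_exceed <= r.n_perm


class TestRankTests:
    def _flies(self, rng, n=50, groups=("yes:none", "no:none", "yes:amw")):
        import pandas as pd

        rows = []
        for g in groups:
            pred, drug = g.split(":")
            for i in range(n):
                rows.append(
                    {
                        "group": g,
                        "turn_bias": rng.beta(8, 8),
                        "turn_rate": rng.gamma(9, 1 / 3),
                    }
                )
        return pd.DataFrame(rows)

    def test_report_structure(self):
        rng = np.random.default_rng(7)
        rep = rank_tests(self._flies(rng))
        assert set(rep["wilcoxon_vs_half"]) == {"yes:none", "no:none", "yes:amw"}
        assert rep["kruskal_wallis"]["p"] > 0
        assert len(rep["turn_rate_mannwhitney"]) == 3
        for rec in rep["turn_rate_mannwhitney"]:
            assert rec["p_adjusted"] >= rec["p_raw"] - 1e-12

    def test_wilcoxon_false_positive_rate_is_nominal(self):
        # biases symmetric around 0.5: rejections should track alpha = 0.05
        rng = np.random.default_rng(8)
        n_rep, rej = 400, 0
        for _ in range(n_rep):
            d = rng.beta(8, 8, 60) - 0.5
            rej += stats.wilcoxon(d)[1] <= 0.05
        lo, hi = stats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_mannwhitney_p_uniform_under_null(self):
        rng = np.random.default_rng(9)
        ps = [
            stats.mannwhitneyu(
                rng.gamma(9, 1 / 3, 40), rng.gamma(9, 1 / 3, 40),
                alternative="two-sided",
            )[1]
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform")[1] > 0.01

    def test_single_fly_groups_are_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(10)
        flies = self._flies(rng, n=1, groups=("yes:none",))
        with caplog.at_level(logging.WARNING, logger="ymaze.variability"):
            rep = rank_tests(flies)
        assert rep["groups"] == []
        assert "fewer than 2 flies" in caplog.text
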