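"""Rank-test chain against hand values, brute-force oracles and scipy/statsmodels."""

import itertools
import logging
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from ctcontrast import benjamini_hochberg, dunn_bh, dunn_test, kruskal_wallis
from ctcontrast.group_stats import midranks

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- oracles


def oracle_ranks(values):
    """Midranks via direct definition: 1 + #smaller + (#equal - 1)/2."""
    v = list(values)
    return [
        1.0 + sum(x < y for x in v) + (sum(x == y for x in v) - 1) / 2.0 for y in v
    ]


def oracle_h(groups):
    """Tie-corrected Kruskal-Wallis H computed from scratch."""
    labels = list(groups)
    pooled = [x for g in labels for x in groups[g]]
    n = len(pooled)
    ranks = oracle_ranks(pooled)
    h = 0.0
    start = 0
    for g in labels:
        ni = len(groups[g])
        rbar = sum(ranks[start : start + ni]) / ni
        h += ni * (rbar - (n + 1) / 2.0) ** 2
        start += ni
    h *= 12.0 / (n * (n + 1))
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


# ---------------------------------------------------------------- Kruskal-Wallis


class TestKruskalWallis:
    def test_hand_computed_two_group_h(self):
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        # ranks 1..6, mean ranks 2 and 5: H = 12/42 * (3*2.25 + 3*2.25) = 27/7
        assert h == pytest.approx(27.0 / 7.0, abs=1e-9)
        assert p == pytest.approx(float(scipy.stats.chi2.sf(27.0 / 7.0, 1)), abs=1e-12)

    def test_interleaved_groups_with_equal_mean_ranks_give_zero(self):
        h, _ = kruskal_wallis({"a": [1, 4, 5, 8], "b": [2, 3, 6, 7]})
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            sizes = rng.integers(2, 6, size=rng.integers(2, 4))
            groups = {
                f"g{i}": rng.integers(0, 6, size=n).astype(float).tolist()
                for i, n in enumerate(sizes)
            }
            pooled = [x for v in groups.values() for x in v]
            if len(set(pooled)) < 2:
                continue  # all values identical: statistic undefined
            h, p = kruskal_wallis(groups)
            assert h == pytest.approx(oracle_h(groups), abs=1e-9)
            hs, ps = scipy.stats.kruskal(*groups.values())
            assert h == pytest.approx(float(hs), abs=1e-9)
            assert p == pytest.approx(float(ps), abs=1e-12)

    def test_statistic_matches_permutation_oracle_on_six_values(self):
        """Exhaustively reassign 6 values to groups of 3+3: H always matches,
        and the exact permutation p-value is logged next to the chi-square one."""
        values = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        observed, chi2_p = kruskal_wallis({"a": values[:3], "b": values[3:]})
        stats = []
        for idx in itertools.combinations(range(6), 3):
            a = [values[i] for i in idx]
            b = [values[i] for i in range(6) if i not in idx]
            g = {"a": a, "b": b}
            h, _ = kruskal_wallis(g)
            assert h == pytest.approx(oracle_h(g), abs=1e-9)
            stats.append(h)
        perm_p = sum(s >= observed - 1e-12 for s in stats) / len(stats)
        logger.info("N=6 exact permutation p = %.4f vs chi-square p = %.4f", perm_p, chi2_p)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 50), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 50), min_size=2, max_size=8),
    )
    def test_invariant_under_strictly_monotone_transform(self, a, b):
        groups = {"a": [float(x) for x in a], "b": [float(x) for x in b]}
        if len(set(a + b)) < 2:
            return  # degenerate: statistic undefined
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(
            {k: [math.exp(0.1 * x) for x in v] for k, v in groups.items()}
        )
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis({"a": [], "b": [1.0]})
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis({"a": [1.0, 2.0]})


# ---------------------------------------------------------------- Dunn


class TestDunn:
    def test_hand_computed_z(self):
        res = dunn_test({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert len(res) == 1
        # z = (2 - 5)/sqrt(3.5 * 2/3), two-sided normal tail
        expected = -3.0 / math.sqrt(3.5 * (2.0 / 3.0))
        assert res[0].z == pytest.approx(expected, abs=1e-9)
        assert abs(res[0].z) == pytest.approx(1.964, abs=5e-4)
        assert res[0].p_raw == pytest.approx(
            2 * scipy.stats.norm.sf(abs(expected)), abs=1e-12
        )

    def test_group_order_flips_sign_not_p(self):
        r1 = dunn_test({"a": [1, 2, 3], "b": [4, 5, 6]})[0]
        r2 = dunn_test({"b": [4, 5, 6], "a": [1, 2, 3]})[0]
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.p_raw == pytest.approx(r2.p_raw, abs=1e-12)

    def test_equal_mean_ranks_give_zero_z_and_p_one(self):
        r = dunn_test({"a": [1, 4, 5, 8], "b": [2, 3, 6, 7]})[0]
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p_raw == pytest.approx(1.0, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            dunn_test({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_three_group_pairs_and_bh_fill(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [2.5, 3.5, 4.5]}
        res = dunn_bh(groups)
        assert [(r.group_a, r.group_b) for r in res] == [("a", "b"), ("a", "c"), ("b", "c")]
        assert benjamini_hochberg([r.p_raw for r in res]) == [r.p_adjusted for r in res]


# ---------------------------------------------------------------- BH


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert benjamini_hochberg([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.04, 0.04], abs=1e-12
        )

    def test_single_and_equal_p_identities(self):
        assert benjamini_hochberg([0.2]) == [pytest.approx(0.2)]
        assert benjamini_hochberg([0.07, 0.07, 0.07]) == pytest.approx(
            [0.07, 0.07, 0.07]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_never_below_raw_capped_rank_monotone_and_matches_statsmodels(self, ps):
        adj = benjamini_hochberg(ps)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        order = np.argsort(ps, kind="stable")
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(len(ps) - 1)
        )
        _, sm_adj, _, _ = multipletests(ps, method="fdr_bh")
        assert adj == pytest.approx(sm_adj.tolist(), abs=1e-12)


def test_midranks_match_definition_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        v = rng.integers(0, 5, size=rng.integers(1, 12)).astype(float)
        assert midranks(v).tolist() == pytest.approx(oracle_ranks(v))
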