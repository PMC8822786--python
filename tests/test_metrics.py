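"""Pair-counting and information-theoretic metric correctness.

The pair-count path is checked against brute-force enumeration of all
unordered cell pairs, and the printed-formula ARI against the independent
contingency-table implementation in scikit-learn.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, fowlkes_mallows_score

from scstab import metrics as M
from scstab.ensemble import Partition


def brute_force_pair_counts(u, v):
    """Independent oracle: classify every unordered pair explicitly."""
    n11 = n00 = n01 = n10 = 0
    for i, j in itertools.combinations(range(len(u)), 2):
        same_u, same_v = u[i] == u[j], v[i] == v[j]
        if same_u and same_v:
            n11 += 1
        elif not same_u and not same_v:
            n00 += 1
        elif same_u:
            n01 += 1
        else:
            n10 += 1
    return n11, n00, n01, n10


labels_pair = st.integers(min_value=2, max_value=12).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
    )
)


class TestPairCounts:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 1, 2, 2], [1, 1, 2, 2], (2, 4, 0, 0)),
            ([1, 1, 2, 2], [1, 2, 1, 2], (0, 2, 2, 2)),
            ([1, 1, 1, 2, 2], [1, 1, 2, 2, 2], (2, 4, 2, 2)),
        ],
    )
    def test_worked_examples(self, u, v, expected):
        pc = M.pair_counts(u, v)
        assert (pc.N11, pc.N00, pc.N01, pc.N10) == expected

    @settings(derandomize=True, max_examples=200)
    @given(labels_pair)
    def test_matches_brute_force_and_conserves(self, uv):
        u, v = uv
        pc = M.pair_counts(u, v)
        assert (pc.N11, pc.N00, pc.N01, pc.N10) == brute_force_pair_counts(u, v)
        n = len(u)
        assert pc.N11 + pc.N00 + pc.N01 + pc.N10 == n * (n - 1) // 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            M.pair_counts([1, 2], [1, 2, 3])

    def test_accepts_partition_objects(self):
        pc = M.pair_counts(Partition([1, 1, 2, 2]), Partition(["a", "a", "b", "b"]))
        assert pc.N11 == 2 and pc.N01 == 0 and pc.N10 == 0


class TestIndices:
    @pytest.mark.parametrize(
        "u, v, e_ari, e_fm, e_jac",
        [
            ([1, 1, 2, 2], [1, 1, 2, 2], 1.0, 1.0, 1.0),
            ([1, 1, 2, 2], [1, 2, 1, 2], -0.5, 0.0, 0.0),
            ([1, 1, 1, 2, 2], [1, 1, 2, 2, 2], 1 / 6, 0.5, 1 / 3),
        ],
    )
    def test_worked_examples(self, u, v, e_ari, e_fm, e_jac):
        assert M.ari(u, v) == pytest.approx(e_ari, abs=1e-12)
        assert M.fm(u, v) == pytest.approx(e_fm, abs=1e-12)
        assert M.jaccard(u, v) == pytest.approx(e_jac, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(labels_pair)
    def test_ari_agrees_with_sklearn(self, uv):
        u, v = uv
        assert M.ari(u, v) == pytest.approx(adjusted_rand_score(u, v), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(labels_pair)
    def test_fm_agrees_with_sklearn(self, uv):
        u, v = uv
        pc = M.pair_counts(u, v)
        if pc.N11 + pc.N01 > 0 and pc.N11 + pc.N10 > 0:
            assert M.fm(u, v) == pytest.approx(fowlkes_mallows_score(u, v), abs=1e-9)

    def test_relabelling_and_reordering_invariance(self, rng):
        u = rng.integers(0, 4, size=30)
        v = rng.integers(0, 3, size=30)
        relab_u = np.array([(9 - x) * 7 for x in u])
        perm = rng.permutation(30)
        for f in (M.ari, M.fm, M.jaccard, M.nmi):
            assert f(u, v) == pytest.approx(f(relab_u, v), abs=1e-12)
            assert f(u, v) == pytest.approx(f(u[perm], v[perm]), abs=1e-12)

    def test_expected_ari_near_zero_for_independent_partitions(self, rng):
        vals = []
        for _ in range(1000):
            u = rng.integers(0, 4, size=50)
            v = rng.integers(0, 4, size=50)
            vals.append(M.ari(u, v))
        assert abs(np.mean(vals)) < 0.02

    def test_degenerate_identical_partitions_score_one(self):
        one_cluster = [0] * 5
        singletons = list(range(5))
        for labels in (one_cluster, singletons):
            assert M.ari(labels, labels) == 1.0
            assert M.fm(labels, labels) == 1.0
            assert M.jaccard(labels, labels) == 1.0


class TestNMI:
    def test_identical_partitions(self):
        assert M.nmi([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert M.nmi([1, 1, 2, 2], [1, 1, 2, 2], "as_printed") == pytest.approx(0.5)

    def test_crossed_partitions_zero(self):
        assert M.nmi([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0, abs=1e-12)
        assert M.nmi([1, 1, 2, 2], [1, 2, 1, 2], "as_printed") == pytest.approx(0.0, abs=1e-12)

    def test_entropy_stats_worked_example(self):
        es = M.entropy_stats([1, 1, 2, 2], [1, 1, 2, 2])
        assert es.I_UV == pytest.approx(1.0)  # bits
        assert es.H_U == pytest.approx(1.0) and es.H_V == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100)
    @given(labels_pair)
    def test_mi_bounded_by_entropies(self, uv):
        u, v = uv
        es = M.entropy_stats(u, v)
        assert -1e-9 <= es.I_UV <= min(es.H_U, es.H_V) + 1e-9

    def test_single_cluster_edge_cases(self):
        # one trivial partition: zero mutual information, positive denominator
        assert M.nmi([0, 0, 0], [0, 1, 2]) == 0.0
        # both trivial: zero total entropy, identical up to relabelling
        assert M.nmi([0, 0, 0], [5, 5, 5]) == 1.0

    def test_unknown_normalization_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            M.nmi([0, 1], [0, 1], "bogus")


class TestDeviationStats:
    def test_single_estimate(self):
        d = M.deviation_stats([12], 10)
        assert d.deviation == 2 and d.relative_deviation == pytest.approx(0.2)
        assert d.sd_estimate == 0.0

    def test_constant_estimates_have_zero_sd(self):
        assert M.deviation_stats([10, 10, 10], 10).sd_estimate == 0.0

    def test_symmetric_estimates(self):
        d = M.deviation_stats([8, 10, 12], 10)
        assert d.sd_estimate == pytest.approx(2.0)
        assert d.relative_deviation == pytest.approx(0.0)
        assert d.deviations == (-2, 0, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.deviation_stats([], 10)

    def test_sign_convention(self):
        assert M.deviation_stats([13], 10).deviation > 0  # over-estimation positive


def test_pair_counts_conservation_enforced():
    with pytest.raises(ValueError, match="N"):
        M.PairCounts(N11=1, N00=1, N01=1, N10=1, N=4)
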