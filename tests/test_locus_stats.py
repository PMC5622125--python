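"""Fisher/FDR, Gower and UPGMA checks.

The multi-group Fisher oracle values below were frozen from R's
fisher.test (r-base 4.3), which implements the exact network algorithm
for r x c tables; the 2 x 2 oracle is a direct hypergeometric
enumeration coded here.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from msapkit import (ConfigurationError, DistanceMatrix, UndefinedValueError,
                     adjust_bh, call_methylation_types, classify_loci,
                     fisher_exact_2xg, gower_distance, intersect_significant,
                     locus_fisher_tests, upgma_cluster)
from msapkit.locus_stats import LocusTestTable
from msapkit.simulate import MsapSimConfig, simulate_msap

from conftest import make_dataset


def hypergeom_2x2_p(table):
    """Two-sided Fisher p for a 2x2 table by direct enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2xg([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_separated_table(self):
        # [[3,0],[0,3]]: enumeration gives 2/C(6,3) = 0.1
        assert fisher_exact_2xg([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_2x2_equals_hypergeometric_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_2xg(t) == pytest.approx(hypergeom_2x2_p(t),
                                                        abs=1e-10)

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[2, 3, 4], [5, 1, 2]], 0.2628547922665556),
            ([[10, 3, 5], [2, 9, 5]], 0.01590048379385649),
            ([[8, 11, 7, 2], [13, 4, 12, 9]], 0.03292215423925473),
        ],
    )
    def test_multigroup_matches_r_fisher_test(self, table, expected):
        assert fisher_exact_2xg(table) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_exact_2xg([[0, 0], [3, 4]]) == 1.0

    def test_monte_carlo_agrees_with_enumeration(self):
        from msapkit.locus_stats import _montecarlo_2xg_p
        t = np.array([[10, 3, 5], [2, 9, 5]], dtype=float)
        p_mc = _montecarlo_2xg_p(t, np.random.default_rng(1), draws=40_000)
        assert p_mc == pytest.approx(0.01590048379385649, abs=0.004)


class TestAdjustBH:
    def test_step_up_hand_computation(self):
        out = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert out.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3]).tolist() == [0.3]

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_manual_step_up_on_random_input(self):
        rng = np.random.default_rng(2)
        p = rng.random(25)
        out = adjust_bh(p)
        # manual step-up: sort, scale by m/rank, cumulative min from top
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        monotone = np.minimum.accumulate(scaled[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(monotone, 1.0)
        np.testing.assert_allclose(out, manual, atol=1e-12)
        assert (out >= p - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigurationError):
            adjust_bh([0.5, 1.5])


class TestLocusFisherTests:
    def test_significant_count_decreases_with_alpha(self, sim_dataset):
        ds, _ = sim_dataset
        _, binm = classify_loci(call_methylation_types(ds))
        n_sig = [len(locus_fisher_tests(binm, alpha=a).significant_loci)
                 for a in (0.2, 0.05, 0.01)]
        assert n_sig == sorted(n_sig, reverse=True)

    def test_contingency_counts_and_adjustment(self, tiny_dataset):
        _, binm = classify_loci(
            call_methylation_types(tiny_dataset), 0.0)
        table = locus_fisher_tests(binm, alpha=0.05)
        for locus in table.locus_ids:
            cont = table.contingency[locus]
            assert cont.to_numpy().sum() == 6  # all samples counted
        assert (table.p_adj >= table.p_raw - 1e-12).all()

    def test_detects_differentiated_loci(self, sim_dataset):
        ds, truth = sim_dataset
        _, binm = classify_loci(call_methylation_types(ds))
        table = locus_fisher_tests(binm, alpha=0.05)
        sig = set(table.significant_loci)
        assert sig  # a strong simulated effect yields discoveries
        # discoveries should be overwhelmingly true differentiated loci
        assert len(sig & truth.differentiated_locus_ids) / len(sig) > 0.8


def _mk_table(sig, universe):
    s = pd.Series([l in sig for l in universe], index=universe)
    p = pd.Series([0.001 if l in sig else 0.9 for l in universe], index=universe)
    return LocusTestTable(list(universe), {}, p, p, s, 0.05)


class TestIntersectSignificant:
    def test_disjoint_significant_sets(self):
        u = [f"L{i}" for i in range(6)]
        assert intersect_significant(_mk_table({"L0"}, u), _mk_table({"L5"}, u)) == set()

    def test_subset_returns_smaller_set(self):
        u = [f"L{i}" for i in range(6)]
        a = _mk_table({"L1", "L2"}, u)
        b = _mk_table({"L1", "L2", "L3"}, u)
        assert intersect_significant(a, b) == {"L1", "L2"}

    def test_disjoint_namespaces_warn_and_return_empty(self, caplog):
        a = _mk_table({"L1"}, ["L1", "L2"])
        b = _mk_table({"M1"}, ["M1", "M2"])
        with caplog.at_level("WARNING"):
            assert intersect_significant(a, b) == set()
        assert "disjoint" in caplog.text


class TestGowerDistance:
    def _types_matrix(self, cols):
        arr = np.array(cols, dtype=float).T
        pat = {1: (1, 1), 2: (0, 1), 3: (1, 0), 4: (0, 0)}
        hpa = np.vectorize(lambda v: np.nan if np.isnan(v) else pat[int(v)][0], otypes=[float])(arr)
        msp = np.vectorize(lambda v: np.nan if np.isnan(v) else pat[int(v)][1], otypes=[float])(arr)
        return call_methylation_types(make_dataset(hpa, msp, ["A"] * arr.shape[0]))

    def test_identical_profiles_zero(self):
        t = self._types_matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert gower_distance(t).d2[0, 1] == 0.0

    def test_fully_different_profiles_one(self):
        t = self._types_matrix([[1, 2, 3, 4], [2, 3, 4, 1]])
        assert gower_distance(t).d2[0, 1] == 1.0

    def test_half_different(self):
        t = self._types_matrix([[1, 2, 3, 4], [1, 2, 4, 1]])
        assert gower_distance(t).d2[0, 1] == 0.5

    def test_missing_cells_excluded_pairwise(self):
        t = self._types_matrix([[1, 2, np.nan, 4], [1, 3, 2, np.nan]])
        # jointly observed: samples 1, 2 -> 1 of 2 differ
        assert gower_distance(t).d2[0, 1] == 0.5

    def test_triangle_inequality_on_complete_data(self):
        rng = np.random.default_rng(3)
        cols = rng.integers(1, 5, size=(8, 12)).tolist()
        d = gower_distance(self._types_matrix(cols)).d2
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_no_joint_sample_pair_errors(self):
        t = self._types_matrix([[1, np.nan], [np.nan, 2]])
        with pytest.raises(UndefinedValueError):
            gower_distance(t)


def naive_upgma(labels, d):
    """O(n^3) UPGMA recomputing every inter-cluster mean from leaf pairs."""
    d = np.asarray(d, dtype=float)
    clusters = [[i] for i in range(len(labels))]
    ids = list(range(len(labels)))
    merges = []
    nxt = len(labels)
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                mean = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                key = (mean,
                       min(labels[i] for i in clusters[a] + clusters[b]),
                       max(min(labels[i] for i in clusters[a]),
                           min(labels[i] for i in clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (mean, _, _), a, b = best
        merges.append((ids[a], ids[b], mean / 2.0))
        clusters[a] = clusters[a] + clusters[b]
        ids[a] = nxt
        nxt += 1
        del clusters[b], ids[b]
    return merges


class TestUpgma:
    def test_two_leaves(self):
        dist = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma_cluster(dist)
        assert tree.merges == [(0, 1, 1.5)]
        assert tree.to_newick() == "(A:1.5,B:1.5);"

    def test_three_leaf_hand_computation(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=6 -> ((A,B),C), heights 1 and 2.5
        d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        tree = upgma_cluster(DistanceMatrix(["A", "B", "C"], d))
        assert tree.merges[0] == (0, 1, 1.0)
        a, b, h = tree.merges[1]
        assert {a, b} == {2, 3} and h == pytest.approx(2.5)
        assert tree.to_newick() == "((A:1,B:1):1.5,C:2.5);"

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 6
            x = rng.random((n, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            labels = [f"T{i}" for i in range(n)]
            mine = upgma_cluster(DistanceMatrix(labels, d)).merges
            ref = naive_upgma(labels, d)
            for (a1, b1, h1), (a2, b2, h2) in zip(mine, ref):
                assert {a1, b1} == {a2, b2}
                assert h1 == pytest.approx(h2)

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(5)
        x = rng.random((7, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = [f"T{i}" for i in range(7)]
        mine = upgma_cluster(DistanceMatrix(labels, d))
        Z = linkage(squareform(d), method="average")
        np.testing.assert_allclose(
            sorted(h for _, _, h in mine.merges),
            sorted(Z[:, 2] / 2.0), atol=1e-12)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(6)
        x = rng.random((9, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        tree = upgma_cluster(DistanceMatrix([f"T{i}" for i in range(9)], d))
        heights = [h for _, _, h in tree.merges]
        assert heights == sorted(heights)

    def test_rejects_non_finite(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ConfigurationError):
            upgma_cluster(DistanceMatrix(["A", "B"], d))
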