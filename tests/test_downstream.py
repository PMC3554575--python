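import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from mirpath import (
    AnnotationList,
    enrichment_curve,
    fisher_exact_2x2,
    hypergeom_overlap,
    overlap_summary,
    round_half_up,
    ward_cluster_binary,
)


def annotation(members):
    return AnnotationList(name="feat", members=frozenset(members))


class TestRoundHalfUp:
    def test_half_rounds_up(self):
        assert round_half_up(0.05) == 0.1
        assert round_half_up(59.25) == 59.3
        assert round_half_up(2.5, 0) == 3.0

    def test_banker_rounding_not_used(self):
        # float round() would give 0.2 for 0.25; half-up gives 0.3
        assert round_half_up(0.25) == 0.3

    def test_published_style_percentages(self):
        assert round_half_up(100 * 99 / 171) == 57.9
        assert round_half_up(100 * 99 / 156) == 63.5
        assert round_half_up(100 * 182 / 265) == 68.7
        assert round_half_up(100 * 182 / 322) == 56.5


class TestEnrichmentCurve:
    def test_feature_equals_top_group_saturates(self):
        """Feature = the miRs with the most pathways: observed overlap is the
        whole group, so E(k) = |group| / (|group| * |feat| / |U|) = |U|/|feat|
        in expectation at high k."""
        counts = pd.Series({f"m{i}": (10 if i < 5 else 1) for i in range(50)})
        universe = set(counts.index)
        feat = annotation([f"m{i}" for i in range(5)])
        curve = enrichment_curve(counts, feat, universe, k_range=[5], n_rand=4000, seed=0)
        # expected overlap = 5 * 5/50 = 0.5 -> E = 5/0.5 = 10
        assert curve.observed == [5]
        assert curve.expected[0] == pytest.approx(0.5, abs=0.05)
        assert curve.enrichment[0] == pytest.approx(10.0, rel=0.1)

    def test_expected_matches_hypergeometric_mean(self):
        """Monte Carlo expected count converges to |group|*|feat|/|U|."""
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.integers(1, 6, size=30), index=[f"m{i}" for i in range(30)])
        universe = set(counts.index)
        feat = annotation(list(rng.choice(sorted(universe), size=8, replace=False)))
        curve = enrichment_curve(counts, feat, universe, n_rand=4000, seed=2)
        for k, size, exp in zip(curve.k_values, curve.group_sizes, curve.expected):
            assert exp == pytest.approx(size * 8 / 30, abs=0.1)

    def test_truncates_at_first_empty_group(self):
        counts = pd.Series({"m0": 2, "m1": 2, "m2": 1})
        universe = {"m0", "m1", "m2", "m3"}
        curve = enrichment_curve(counts, annotation(["m0"]), universe,
                                 k_range=[1, 2, 3, 4], n_rand=200, seed=0)
        assert curve.k_values == [1, 2]

    def test_feature_outside_universe_rejected(self):
        counts = pd.Series({"m0": 1})
        with pytest.raises(ValueError):
            enrichment_curve(counts, annotation(["zz"]), {"m0"}, n_rand=10)


class TestHypergeomOverlap:
    def test_worked_one_over_252(self):
        # both sets of size 5 in a universe of 10, full overlap: p = 1/C(10,5)
        universe = {f"x{i}" for i in range(10)}
        a = {f"x{i}" for i in range(5)}
        assert hypergeom_overlap(a, a, universe) == pytest.approx(1 / 252)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"x{i}" for i in range(10)}
        a = {"x0", "x1"}
        b = {"x5", "x6"}
        assert hypergeom_overlap(a, b, universe) == pytest.approx(
            stats.hypergeom.sf(-1, 10, 2, 2)
        )
        assert hypergeom_overlap(a, b, universe) == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        """p equals the literal sum over all equally likely draws of B."""
        universe = sorted(f"x{i}" for i in range(9))
        a = set(universe[:4])
        for nb in (2, 3, 5):
            b = set(universe[2 : 2 + nb])
            observed = len(a & b)
            total = hits = 0
            for draw in itertools.combinations(universe, nb):
                total += 1
                if len(a & set(draw)) >= observed:
                    hits += 1
            assert hypergeom_overlap(a, b, set(universe)) == pytest.approx(hits / total)

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            hypergeom_overlap({"a"}, {"b"}, {"b"})
        with pytest.raises(ValueError):
            hypergeom_overlap(set(), set(), set())


class TestFisherExact:
    def test_worked_value(self):
        assert fisher_exact_2x2([[1, 9], [11, 3]]) == pytest.approx(0.002759, abs=1e-5)

    def test_oracle_random_tables(self):
        """Two-sided p equals the sum of probabilities of all tables with the
        same margins whose probability does not exceed the observed one."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            a, b, c, d = t.ravel()
            r1, r2, c1 = a + b, c + d, a + c
            n = r1 + r2

            def table_p(x):
                return (
                    math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
                )

            lo, hi = max(0, c1 - r2), min(r1, c1)
            p_obs = table_p(a)
            p_two = sum(
                table_p(x) for x in range(lo, hi + 1) if table_p(x) <= p_obs * (1 + 1e-9)
            )
            assert fisher_exact_2x2(t) == pytest.approx(p_two, rel=1e-6)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [3, 4]])


class TestOverlapSummary:
    def test_three_condition_worked_percentages(self):
        """167/171/156 IMs with a common core of 99 gives 59.3/57.9/63.5."""
        core = {f"core{i}" for i in range(99)}
        im_sets = {
            "A": core | {f"a{i}" for i in range(68)},   # 167
            "B": core | {f"b{i}" for i in range(72)},   # 171
            "C": core | {f"c{i}" for i in range(57)},   # 156
        }
        s = overlap_summary(im_sets)
        assert s.oim == core
        assert s.oim_percentages == {"A": 59.3, "B": 57.9, "C": 63.5}

    def test_pairs_and_pathways_intersected(self):
        im_sets = {"A": {"m1", "m2"}, "B": {"m2"}}
        pw = {"A": {"P1", "P2"}, "B": {"P2", "P3"}}
        pairs = {"A": {("m2", "P2"), ("m1", "P1")}, "B": {("m2", "P2")}}
        s = overlap_summary(im_sets, pair_sets=pairs, pathway_sets=pw)
        assert s.shared_pathways == {"P2"}
        assert s.shared_pairs == {("m2", "P2")}
        assert s.pathway_percentages == {"A": 50.0, "B": 50.0}

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            overlap_summary({"A": {"m1"}})

    def test_empty_set_reports_zero_percent(self):
        s = overlap_summary({"A": {"m1"}, "B": set()})
        assert s.oim == set()
        assert s.oim_percentages["B"] == 0.0


class TestWardClusterBinary:
    def test_two_block_matrix_recovered(self):
        rows = ["r1", "r2", "r3", "r4"]
        cols = ["c1", "c2", "c3", "c4"]
        m = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=rows, columns=cols, dtype=float,
        )
        res = ward_cluster_binary(m, n_clusters=2)
        assert res.row_labels[0] == res.row_labels[1]
        assert res.row_labels[2] == res.row_labels[3]
        assert res.row_labels[0] != res.row_labels[2]
        assert res.col_labels[0] == res.col_labels[1] != res.col_labels[2]

    def test_matches_scipy_reference_on_random_binary(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 2, size=(7, 5)).astype(float))
        res = ward_cluster_binary(m, n_clusters=3)
        ref = fcluster(linkage(m.to_numpy(), method="ward"), t=3, criterion="maxclust")
        assert (res.row_labels == ref).all()

    def test_reordered_is_a_permutation(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(6, 4)).astype(float),
            index=[f"r{i}" for i in range(6)], columns=[f"c{j}" for j in range(4)],
        )
        res = ward_cluster_binary(m)
        out = res.reordered(m)
        assert sorted(out.index) == sorted(m.index)
        assert sorted(out.columns) == sorted(m.columns)
        assert out.to_numpy().sum() == m.to_numpy().sum()

    def test_single_row_trivial(self):
        m = pd.DataFrame([[1.0, 0.0]], index=["r"], columns=["a", "b"])
        res = ward_cluster_binary(m)
        assert list(res.row_labels) == [1]
        assert list(res.row_order) == [0]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster_binary(pd.DataFrame([[0.5, 1.0], [0.0, 1.0]]))

    def test_row_label_invariance_under_column_permutation(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.integers(0, 2, size=(8, 6)).astype(float))
        perm = rng.permutation(6)
        a = ward_cluster_binary(m, n_clusters=2)
        b = ward_cluster_binary(m.iloc[:, perm], n_clusters=2)
        assert (a.row_labels == b.row_labels).all()
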