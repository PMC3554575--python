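import itertools

import numpy as np
import pytest
from scipy import stats

from mirpath import (
    RankedList,
    SyntheticConfig,
    enrichment_score,
    generate_cohort,
    gsea,
    leading_edge,
    rank_genes,
)
from tests.conftest import make_dataset


def brute_force_walk(ranked_ids, metric, members, p=1.0):
    """Independent step-by-step running-sum walk (the oracle)."""
    hits = [g in members for g in ranked_ids]
    n, n_hit = len(ranked_ids), sum(hits)
    denom_hit = sum(abs(m) ** p for m, h in zip(metric, hits) if h)
    running, acc_hit, acc_miss = [], 0.0, 0.0
    for g, m, h in zip(ranked_ids, metric, hits):
        if h:
            acc_hit += (abs(m) ** p) / denom_hit if denom_hit > 0 else 1.0 / n_hit
        else:
            acc_miss += 1.0 / (n - n_hit)
        running.append(acc_hit - acc_miss)
    # signed extremum; magnitude ties (exact or at float precision) -> positive
    best, best_i = running[0], 0
    for i, v in enumerate(running[1:], start=1):
        if abs(v) > abs(best) + 1e-12 or (abs(v) >= abs(best) - 1e-12 and v > best):
            best, best_i = v, i
    return best, running, best_i + 1


class TestRankGenes:
    def test_signal_to_noise_direct_value(self):
        # one gene: mu_D=2, mu_C=0, sd about 1 in both classes -> metric ~1
        rng = np.random.default_rng(0)
        d = rng.normal(2, 1, 2000)
        c = rng.normal(0, 1, 2000)
        ds = make_dataset(np.concatenate([d, c])[None, :], ["g1"], 2000, 2000)
        ranked = rank_genes(ds)
        assert ranked.metric[0] == pytest.approx(1.0, abs=0.05)

    def test_identical_class_means_gives_lexicographic_order(self):
        vals = np.tile([1.0, 2.0, 1.0, 2.0], (3, 1))
        ds = make_dataset(vals, ["b", "a", "c"], 2, 2)
        ranked = rank_genes(ds)
        assert np.allclose(ranked.metric, 0.0)
        assert ranked.gene_ids == ["a", "b", "c"]

    def test_order_matches_per_gene_arithmetic(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(5, 8))
        ids = ["g1", "g2", "g3", "g4", "g5"]
        ds = make_dataset(vals, ids, 4, 4)
        expected = {}
        for i, g in enumerate(ids):
            d, c = vals[i, :4], vals[i, 4:]
            sd_d = max(d.std(ddof=1), 0.2 * abs(d.mean()))
            sd_c = max(c.std(ddof=1), 0.2 * abs(c.mean()))
            expected[g] = (d.mean() - c.mean()) / (sd_d + sd_c)
        order = sorted(ids, key=lambda g: (-expected[g], g))
        ranked = rank_genes(ds)
        assert ranked.gene_ids == order
        assert ranked.metric == pytest.approx([expected[g] for g in order])


class TestEnrichmentScore:
    def _ranked(self, n=5):
        return RankedList(
            gene_ids=[f"g{i}" for i in range(1, n + 1)],
            metric=np.arange(n, 0, -1, dtype=float),
        )

    def test_top_gene_only_scores_one(self):
        es, _, peak = enrichment_score(self._ranked(), ["g1"])[0:3]
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_worked_five_gene_example(self):
        # metrics (5,4,3,2,1), set {ranks 1,3}: ES=2/3 at peak 3
        es, running, peak = enrichment_score(self._ranked(), ["g1", "g3"])
        assert es == pytest.approx(2.0 / 3.0)
        assert peak == 3
        assert running == pytest.approx([0.625, 0.2917, 0.6667, 0.3333, 0.0], abs=1e-4)

    def test_bottom_gene_negative_with_peak_before_hit(self):
        ranked = self._ranked()
        es, running, peak = enrichment_score(ranked, ["g5"])
        expected_es, expected_run, expected_peak = brute_force_walk(
            ranked.gene_ids, ranked.metric, {"g5"}
        )
        assert es < 0
        assert es == pytest.approx(expected_es)
        assert peak == expected_peak

    def test_exhaustive_oracle_small_sets(self):
        """All sets of size <=4 over ranked lists of length <=8 match the
        independent walk."""
        rng = np.random.default_rng(11)
        for n in (4, 6, 8):
            metric = np.sort(rng.normal(size=n))[::-1]
            ids = [f"g{i}" for i in range(n)]
            ranked = RankedList(gene_ids=ids, metric=metric)
            for k in range(1, 5):
                if k >= n:
                    continue
                for members in itertools.combinations(ids, k):
                    es, running, peak = enrichment_score(ranked, list(members))
                    exp_es, exp_run, exp_peak = brute_force_walk(ids, metric, set(members))
                    assert es == pytest.approx(exp_es), (n, members)
                    assert running == pytest.approx(exp_run)
                    assert peak == exp_peak

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(2)
        metric = np.sort(rng.normal(size=30))[::-1]
        ids = [f"g{i}" for i in range(30)]
        ranked = RankedList(gene_ids=ids, metric=metric)
        for members in (["g0", "g5", "g29"], ["g10"], [f"g{i}" for i in range(0, 30, 3)]):
            _, running, _ = enrichment_score(ranked, members)
            assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_monotone_rescaling_at_p_zero(self):
        ids = [f"g{i}" for i in range(6)]
        metric = np.array([9.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        a = enrichment_score(RankedList(ids, metric), ["g0", "g3"], weight_p=0.0)
        b = enrichment_score(RankedList(ids, metric * 7 + 1), ["g0", "g3"], weight_p=0.0)
        assert a[0] == pytest.approx(b[0])

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="not represented"):
            enrichment_score(self._ranked(), ["absent"])


class TestLeadingEdge:
    def test_worked_example_members_before_peak(self):
        ranked = RankedList([f"g{i}" for i in range(1, 6)], np.arange(5, 0, -1, dtype=float))
        res = enrichment_score(ranked, ["g1", "g3"])
        assert leading_edge(ranked, ["g1", "g3"], res) == ["g1", "g3"]

    def test_single_gene_set(self):
        ranked = RankedList([f"g{i}" for i in range(1, 6)], np.arange(5, 0, -1, dtype=float))
        res = enrichment_score(ranked, ["g2"])
        assert leading_edge(ranked, ["g2"], res) == ["g2"]

    def test_negative_es_takes_members_at_or_after_peak(self):
        ranked = RankedList([f"g{i}" for i in range(1, 6)], np.arange(5, 0, -1, dtype=float))
        members = ["g4", "g5"]
        res = enrichment_score(ranked, members)
        assert res[0] < 0
        leg = leading_edge(ranked, members, res)
        assert leg == ["g4", "g5"]
        assert all(ranked.gene_ids.index(g) + 1 >= res[2] for g in leg)

    def test_membership_and_side_invariant(self, default_cohort):
        genes, _, _, pathways, _ = default_cohort
        ranked = rank_genes(genes)
        pos = {g: i + 1 for i, g in enumerate(ranked.gene_ids)}
        for name in pathways.names()[:10]:
            res = enrichment_score(ranked, pathways[name])
            leg = leading_edge(ranked, pathways[name], res)
            assert set(leg) <= set(pathways[name])
            if res[0] > 0:
                assert all(pos[g] <= res[2] for g in leg)
            elif res[0] < 0:
                assert all(pos[g] >= res[2] for g in leg)


class TestGsea:
    def test_planted_pathways_detected(self):
        """Coherently shifted pathways get positive/negative NES and are
        called differentially expressed at delta=2, 20+20 samples."""
        hits, total = 0, 0
        for seed in range(4):
            genes, _, _, pathways, truth = generate_cohort(SyntheticConfig(seed=seed))
            res = gsea(genes, pathways, n_perm=200, seed=seed, min_size=10)
            by_name = {e.pathway_name: e for e in res}
            for pw, direction in truth.dysregulated_pathways.items():
                e = by_name[pw]
                total += 1
                if e.is_de and (e.nes > 0) == (direction == "up"):
                    hits += 1
        assert hits / total >= 0.7

    def test_null_pvalues_roughly_uniform(self, null_cohort):
        genes, _, _, pathways, _ = null_cohort
        res = gsea(genes, pathways, n_perm=200, seed=3, min_size=10)
        pvals = [e.p_empirical for e in res]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sign_consistency_and_fdr_flag(self, default_cohort):
        genes, _, _, pathways, _ = default_cohort
        res = gsea(genes, pathways, n_perm=100, seed=0, min_size=10)
        for e in res:
            assert np.sign(e.nes) == np.sign(e.es)
            assert e.is_de == (e.fdr < 0.01)

    def test_small_n_perm_rejected(self, default_cohort):
        genes, _, _, pathways, _ = default_cohort
        with pytest.raises(ValueError, match="n_perm"):
            gsea(genes, pathways, n_perm=5)

    def test_size_filter_can_reject_everything(self, default_cohort):
        genes, _, _, pathways, _ = default_cohort
        with pytest.raises(ValueError, match="size filter"):
            gsea(genes, pathways, n_perm=50, min_size=400)
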