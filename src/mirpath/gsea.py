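"""Gene set enrichment: ranking, running-sum enrichment scores, leading-edge
genes, and permutation-based NES / empirical p / FDR calls for pathways.

The enrichment score is the signed extremum of the weighted Kolmogorov-
Smirnov running sum: hits advance by |r|^p normalized over the set's hits,
misses retreat by 1/(N - |S|). Leading-edge genes are the set members at or
before the peak (for positive scores) or at or after it (negative scores) —
the members that drive the enrichment signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset, GeneSetCollection
from .diffexp import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by descending ranking metric (ties broken by id)."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene_ids and metric must have equal length")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class PathwayEnrichment:
    pathway_name: str
    es: float
    nes: float
    p_empirical: float
    fdr: float
    is_de: bool
    leading_edge: list[str]
    peak_index: int  # 1-based position of the running-sum extremum
    size: int  # measured genes in the set


def _signal_to_noise(values: np.ndarray, disease: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-feature (mu_D - mu_C) / (sd_D + sd_C) with each class sd floored
    at 0.2 * |class mean| (the convention of the classical GSEA tool)."""
    mu_d = values[:, disease].mean(axis=1)
    mu_c = values[:, control].mean(axis=1)
    sd_d = values[:, disease].std(axis=1, ddof=1)
    sd_c = values[:, control].std(axis=1, ddof=1)
    sd_d = np.maximum(sd_d, 0.2 * np.abs(mu_d))
    sd_c = np.maximum(sd_c, 0.2 * np.abs(mu_c))
    denom = sd_d + sd_c
    out = np.zeros(len(values))
    ok = denom > 0
    out[ok] = (mu_d - mu_c)[ok] / denom[ok]
    return out


def _t_metric(values: np.ndarray, disease: np.ndarray, control: np.ndarray) -> np.ndarray:
    from scipy import stats

    t, _ = stats.ttest_ind(values[:, disease], values[:, control], axis=1, equal_var=True)
    return np.nan_to_num(np.asarray(t), nan=0.0)


_METRICS = {"signal_to_noise": _signal_to_noise, "t_stat": _t_metric}


def rank_genes(genes: ExpressionDataset, metric: str = "signal_to_noise") -> RankedList:
    """Rank all genes by a class-separation metric, descending.

    Ties (including the all-zero case when class means coincide) are broken
    lexicographically by gene id so the ranking is always deterministic.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    disease, control = genes.class_masks()
    if disease.sum() < 2 or control.sum() < 2:
        raise ValueError("need >=2 samples per class")
    values = genes.matrix()
    m = _METRICS[metric](values, disease, control)
    order = sorted(range(len(m)), key=lambda i: (-m[i], genes.feature_ids[i]))
    return RankedList(
        gene_ids=[genes.feature_ids[i] for i in order], metric=m[np.array(order)]
    )


def enrichment_score(
    ranked: RankedList, gene_set: list[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted KS running-sum enrichment score of one gene set.

    Returns ``(es, running_sum, peak_index)`` where ``peak_index`` is the
    1-based position of the signed extremum. If every hit carries zero
    metric weight the hit increments fall back to equal weights so the walk
    remains defined.
    """
    hit = np.isin(np.asarray(ranked.gene_ids), list(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set not represented in the ranked list")
    n = len(ranked)
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.metric) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # degenerate all-zero weights: unweighted walk
        hit_w = hit.astype(float)
        total = float(n_hit)
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~hit) / (n - n_hit)
    running = p_hit - p_miss
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # signed extremum; on a magnitude tie (exact, or within float precision
    # of the cumulative sums) prefer the positive deviation
    positive = running[i_max] >= -running[i_min] - 1e-12
    es = float(running[i_max]) if positive else float(running[i_min])
    peak = i_max + 1 if positive else i_min + 1
    return es, running, peak


def leading_edge(
    ranked: RankedList, gene_set: list[str], es_result: tuple[float, np.ndarray, int]
) -> list[str]:
    """Set members on the signal side of the running-sum peak, in rank order.

    A zero enrichment score yields an empty leading edge by convention.
    """
    es, _, peak = es_result
    if es == 0:
        return []
    members = set(gene_set)
    ids = ranked.gene_ids
    if es > 0:
        return [g for g in ids[:peak] if g in members]
    return [g for g in ids[peak - 1 :] if g in members]


def _es_for_sets(
    ranked_ids: list[str], metric: np.ndarray, set_members: list[set[str]], weight_p: float
) -> np.ndarray:
    """Enrichment scores of several sets against one ranking (score only)."""
    n = len(ranked_ids)
    idx = {g: i for i, g in enumerate(ranked_ids)}
    w = np.abs(metric) ** weight_p
    out = np.empty(len(set_members))
    for k, members in enumerate(set_members):
        hit = np.zeros(n, dtype=bool)
        for g in members:
            j = idx.get(g)
            if j is not None:
                hit[j] = True
        n_hit = int(hit.sum())
        hit_w = np.where(hit, w, 0.0)
        total = hit_w.sum()
        if total == 0:
            hit_w = hit.astype(float)
            total = float(n_hit)
        running = np.cumsum(hit_w) / total - np.cumsum(~hit) / (n - n_hit)
        hi, lo = running.max(), running.min()
        out[k] = hi if hi >= -lo else lo
    return out


def gsea(
    genes: ExpressionDataset,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    de_fdr: float = 0.01,
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight_p: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> list[PathwayEnrichment]:
    """Full enrichment analysis of a gene-set collection.

    The null distribution comes from phenotype-label permutations (the
    ranking is recomputed per permutation). When the smaller class has
    fewer than 7 samples, too few distinct label permutations exist and the
    null switches to gene-set permutation on the observed ranking (logged).
    NES divides ES by the mean |null ES| of matching sign; the empirical p
    is the fraction of same-sign null scores at least as extreme; pathway
    FDR is Benjamini-Hochberg over the empirical p-values.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    measured = set(genes.feature_ids)
    filtered: dict[str, list[str]] = {}
    for name, members in sets.sets.items():
        inter = [g for g in members if g in measured]
        if min_size <= len(inter) <= max_size:
            filtered[name] = inter
    if not filtered:
        raise ValueError("no gene set survives the size filter")

    ranked = rank_genes(genes, metric=metric)
    names = list(filtered)
    set_members = [set(filtered[n_]) for n_ in names]
    es_obs = np.empty(len(names))
    peaks: list[tuple[float, np.ndarray, int]] = []
    for k, name in enumerate(names):
        res = enrichment_score(ranked, filtered[name], weight_p)
        es_obs[k] = res[0]
        peaks.append(res)

    rng = np.random.default_rng(seed)
    disease, control = genes.class_masks()
    values = genes.matrix()
    n_samples = values.shape[1]
    n_disease = int(disease.sum())
    use_phenotype = min(n_disease, n_samples - n_disease) >= 7
    if not use_phenotype:
        logger.info("gsea: small class (<7) -> gene-set permutation null")

    null_es = np.empty((n_perm, len(names)))
    metric_fn = _METRICS[metric]
    if use_phenotype:
        for b in range(n_perm):
            perm = rng.permutation(n_samples)
            d_mask = np.zeros(n_samples, dtype=bool)
            d_mask[perm[:n_disease]] = True
            m = metric_fn(values, d_mask, ~d_mask)
            order = np.argsort(-m, kind="stable")  # ties: stable on gene order
            ids = [genes.feature_ids[i] for i in order]
            null_es[b] = _es_for_sets(ids, m[order], set_members, weight_p)
    else:
        all_genes = np.asarray(ranked.gene_ids)
        sizes = [len(filtered[n_]) for n_ in names]
        for b in range(n_perm):
            rand_sets = [
                set(all_genes[rng.choice(len(all_genes), size=s, replace=False)]) for s in sizes
            ]
            null_es[b] = _es_for_sets(ranked.gene_ids, ranked.metric, rand_sets, weight_p)

    results: list[PathwayEnrichment] = []
    pvals = np.empty(len(names))
    nes = np.empty(len(names))
    for k in range(len(names)):
        same = null_es[:, k][np.sign(null_es[:, k]) == np.sign(es_obs[k])]
        if len(same) == 0:
            nes[k] = 0.0
            pvals[k] = 0.0 if es_obs[k] != 0 else 1.0
        else:
            nes[k] = es_obs[k] / np.abs(same).mean()
            pvals[k] = float(np.mean(np.abs(same) >= abs(es_obs[k])))
        if es_obs[k] == 0:
            nes[k] = 0.0
            pvals[k] = 1.0
    qvals = bh_fdr(pvals)
    for k, name in enumerate(names):
        results.append(
            PathwayEnrichment(
                pathway_name=name,
                es=float(es_obs[k]),
                nes=float(nes[k]),
                p_empirical=float(pvals[k]),
                fdr=float(qvals[k]),
                is_de=bool(qvals[k] < de_fdr),
                leading_edge=leading_edge(ranked, filtered[name], peaks[k]),
                peak_index=peaks[k][2],
                size=len(filtered[name]),
            )
        )
    return results
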