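"""Results-level statistics: randomization enrichment curves, set-overlap
summaries across conditions, exact overlap tests, and Ward clustering of
binary association matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .data_io import AnnotationList

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), used for reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentCurve:
    """Enrichment E(k) of a miR feature within groups of important miRs
    linked to at least k pathways, against a label-randomization null."""

    k_values: list[int]
    group_sizes: list[int]
    observed: list[int]
    expected: list[float]  # mean randomized count
    enrichment: list[float]  # observed / expected
    n_rand: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "group_size": self.group_sizes,
                "observed": self.observed,
                "expected": self.expected,
                "enrichment": self.enrichment,
            }
        )


@dataclass
class OverlapSummary:
    """Cross-condition intersections of IMs, pathways and IM/pathway pairs."""

    im_sets: dict[str, set[str]]
    oim: set[str]
    oim_percentages: dict[str, float]  # 100 * |OIM| / |IM_c|, one decimal
    pathway_sets: dict[str, set[str]]
    shared_pathways: set[str]
    pathway_percentages: dict[str, float]
    pair_sets: dict[str, set[tuple[str, str]]]
    shared_pairs: set[tuple[str, str]]


def enrichment_curve(
    pathway_counts: pd.Series,
    feature: AnnotationList,
    universe: set[str],
    k_range: range | list[int] | None = None,
    n_rand: int = 10_000,
    seed: int = 0,
) -> EnrichmentCurve:
    """Enrichment of a miR feature in groups of miRs with >= k pathways.

    For each k the group is the set of miRs with at least k significant
    pathways; the observed count is its overlap with the feature list; the
    null redraws the feature label set uniformly from the universe
    ``n_rand`` times and averages the overlap. E(k) > 1 flags enrichment.
    The curve is truncated (and logged) at the first k with an empty group.
    """
    members = set(feature.members)
    if not members <= universe:
        raise ValueError("feature must be a subset of the candidate universe")
    counts = pathway_counts[pathway_counts.index.isin(universe)]
    if k_range is None:
        k_range = range(1, int(counts.max()) + 1) if len(counts) else range(1, 2)
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    feat_mask = np.array([u in members for u in uni])
    n_feat = int(feat_mask.sum())

    ks, sizes, obs, exp, enr = [], [], [], [], []
    for k in k_range:
        group = set(counts[counts >= k].index)
        if not group:
            logger.info("enrichment_curve: empty group at k=%d, curve truncated", k)
            break
        observed = len(group & members)
        group_mask = np.array([u in group for u in uni])
        # randomized overlap: redraw the feature labels over the universe
        draws = np.empty(n_rand)
        g_idx = np.flatnonzero(group_mask)
        for b in range(n_rand):
            pick = rng.choice(len(uni), size=n_feat, replace=False)
            draws[b] = np.isin(pick, g_idx).sum()
        mean_rand = float(draws.mean())
        if mean_rand == 0:
            logger.info("enrichment_curve: zero expected count at k=%d, truncated", k)
            break
        ks.append(int(k))
        sizes.append(len(group))
        obs.append(observed)
        exp.append(mean_rand)
        enr.append(observed / mean_rand)
    return EnrichmentCurve(
        k_values=ks, group_sizes=sizes, observed=obs, expected=exp, enrichment=enr, n_rand=n_rand
    )


def hypergeom_overlap(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric p of the overlap |A & B| given |universe|."""
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(set_a & set_b)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(set_a), len(set_b)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def overlap_summary(
    im_sets: dict[str, set[str]],
    pair_sets: dict[str, set[tuple[str, str]]] | None = None,
    pathway_sets: dict[str, set[str]] | None = None,
) -> OverlapSummary:
    """Intersections across >= 2 conditions with reported percentages.

    Percentages 100*|intersection|/|per-condition set| are rounded
    half-up to one decimal.
    """
    if len(im_sets) < 2:
        raise ValueError("need >= 2 conditions")
    pair_sets = pair_sets or {c: set() for c in im_sets}
    pathway_sets = pathway_sets or {c: set() for c in im_sets}

    def _intersection(sets: dict) -> set:
        it = iter(sets.values())
        out = set(next(it))
        for s in it:
            out &= set(s)
        return out

    oim = _intersection(im_sets)
    shared_pw = _intersection(pathway_sets)
    shared_pairs = _intersection(pair_sets)
    oim_pct = {
        c: round_half_up(100.0 * len(oim) / len(s)) if s else 0.0 for c, s in im_sets.items()
    }
    pw_pct = {
        c: round_half_up(100.0 * len(shared_pw) / len(s)) if s else 0.0
        for c, s in pathway_sets.items()
    }
    return OverlapSummary(
        im_sets=im_sets,
        oim=oim,
        oim_percentages=oim_pct,
        pathway_sets=pathway_sets,
        shared_pathways=shared_pw,
        pathway_percentages=pw_pct,
        pair_sets=pair_sets,
        shared_pairs=shared_pairs,
    )


@dataclass
class ClusterResult:
    row_labels: np.ndarray  # cluster id per row
    col_labels: np.ndarray
    row_order: np.ndarray  # dendrogram leaf order
    col_order: np.ndarray
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def reordered(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.iloc[self.row_order, self.col_order]


def ward_cluster_binary(matrix: pd.DataFrame, n_clusters: int = 2) -> ClusterResult:
    """Ward agglomerative clustering of a binary matrix, rows and columns
    independently, on Euclidean distances.

    Leaf order comes from scipy's deterministic dendrogram traversal; a
    single row (or column) trivially forms one cluster.
    """
    values = matrix.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty matrix")
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("matrix entries must be binary")

    def _side(v: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if v.shape[0] == 1:
            return np.array([1]), np.array([0]), np.empty((0, 4))
        link = linkage(v, method="ward")
        labels = fcluster(link, t=min(k, v.shape[0]), criterion="maxclust")
        return labels, leaves_list(link), link

    row_labels, row_order, row_link = _side(values, n_clusters)
    col_labels, col_order, col_link = _side(values.T, n_clusters)
    return ClusterResult(
        row_labels=row_labels,
        col_labels=col_labels,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )
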