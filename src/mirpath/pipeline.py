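"""End-to-end orchestration: per-condition analysis (enrichment -> leading
edges -> targeting profiles -> forest importance -> permutation null -> IM
calls -> correlation change) and the multi-condition comparison that
intersects IM sets into overall important miRs (OIMs).

Two named parameter presets exist: ``full`` mirrors the published protocol
(10,000 trees, 100 null replicates, 1,000 enrichment permutations) and
``scaled`` is a seconds-to-minutes profile for iteration and CI-sized runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corr_change, data_io, downstream, importance, profiles
from .diffexp import DEResult, differential_expression
from .gsea import PathwayEnrichment
from .gsea import gsea as run_gsea

logger = logging.getLogger(__name__)

PRESETS: dict[str, dict[str, int]] = {
    "full": {"n_perm": 1000, "n_trees": 10_000, "n_null": 100},
    "scaled": {"n_perm": 200, "n_trees": 500, "n_null": 20},
}


@dataclass
class RunConfig:
    """All inputs and thresholds of one condition run."""

    gene_matrix: str = ""
    mir_matrix: str = ""
    phenotype: str = ""
    interactions: str = ""
    pathways: str = ""
    name: str = "condition"
    # GSEA
    n_perm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    weight_p: float = 1.0
    metric: str = "signal_to_noise"
    # forest
    n_trees: int = 10_000
    n_null: int = 100
    mtry: int | None = None
    case_fraction: float = 2.0 / 3.0
    # thresholds
    pathway_de_fdr: float = 0.01
    mir_de_fdr: float = 0.01
    im_fdr: float = 0.01
    deltaz_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.pathway_de_fdr, self.mir_de_fdr, self.im_fdr):
            if not 0 < thr < 1:
                raise ValueError("FDR thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        preset = data.pop("preset", None)
        cfg = cls(**data)
        if preset:
            cfg = cfg.with_preset(preset)
        return cfg

    def with_preset(self, name: str) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}")
        params = asdict(self) | PRESETS[name]
        return RunConfig(**params)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def validate_paths(self) -> None:
        for attr in ("gene_matrix", "mir_matrix", "phenotype", "interactions", "pathways"):
            p = getattr(self, attr)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p!r} does not exist")


@dataclass
class ConditionBundle:
    """All per-condition stage outputs."""

    name: str
    enrichments: list[PathwayEnrichment]
    de_mirs: list[DEResult]
    profile: profiles.MiRProfileMatrix
    significance: importance.SignificanceResult
    deltaz: list[corr_change.DeltaZRecord]
    config_hash: str = ""
    seed: int = 0

    @property
    def ims(self) -> set[str]:
        return self.significance.ims

    @property
    def significant_pathways(self) -> set[str]:
        return self.significance.significant_pathways

    @property
    def significant_pairs(self) -> set[tuple[str, str]]:
        sig = self.significance.significant_pairs
        return set(zip(sig["mir"], sig["pathway"]))

    @property
    def de_pathways(self) -> set[str]:
        return {e.pathway_name for e in self.enrichments if e.is_de}

    def enrichment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.pathway_name,
                    e.es,
                    e.nes,
                    e.p_empirical,
                    e.fdr,
                    e.is_de,
                    len(e.leading_edge),
                    ";".join(e.leading_edge),
                )
                for e in self.enrichments
            ],
            columns=["pathway", "es", "nes", "p", "fdr", "is_de", "n_leg", "leading_edge"],
        )

    def de_mir_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.feature_id, r.t, r.p, r.q, r.is_de) for r in self.de_mirs],
            columns=["feature", "t", "p", "q", "is_de"],
        )


def analyze_condition(
    genes: data_io.ExpressionDataset,
    mirs: data_io.ExpressionDataset,
    network: data_io.InteractionNetwork,
    pathways: data_io.GeneSetCollection,
    config: RunConfig,
) -> ConditionBundle:
    """Run the full per-condition pipeline on in-memory inputs."""

    def stage(msg: str):
        logger.info("[%s] %s", config.name, msg)
        return time.perf_counter()

    t0 = stage("gsea")
    enrichments = run_gsea(
        genes,
        pathways,
        n_perm=config.n_perm,
        de_fdr=config.pathway_de_fdr,
        seed=config.stage_seed("gsea"),
        metric=config.metric,
        weight_p=config.weight_p,
        min_size=config.gsea_min_size,
        max_size=config.gsea_max_size,
    )

    stage(f"gsea done in {time.perf_counter() - t0:.1f}s; de mirs")
    de_mirs = differential_expression(mirs, alpha_fdr=config.mir_de_fdr)

    t0 = stage("profiles")
    profile = profiles.zscore_profiles(profiles.leg_count_matrix(enrichments, network))
    nes = pd.Series(
        {e.pathway_name: e.nes for e in enrichments if e.pathway_name in profile.pathways}
    ).reindex(profile.pathways)

    t0 = stage("forest + permutation null")
    fc = importance.ForestConfig(
        n_trees=config.n_trees,
        mtry=config.mtry,
        case_fraction=config.case_fraction,
        n_null=config.n_null,
        seed=config.stage_seed("forest"),
    )
    L = importance.fit_forest(profile, nes, fc)
    null_stats = importance.permutation_null(profile, nes, fc)
    significance = importance.call_im_pairs(L, null_stats, alpha_fdr=config.im_fdr)

    t0 = stage(f"importance done in {time.perf_counter() - t0:.1f}s; correlation change")
    leg_by_pathway = {e.pathway_name: set(e.leading_edge) for e in enrichments}
    edge_filter: set[tuple[str, str]] = set()
    sig = significance.significant_pairs
    targets = network.targets_by_mir()
    for mir, pw in zip(sig["mir"], sig["pathway"]):
        for gene in targets.get(mir, ()) & leg_by_pathway.get(pw, set()):
            edge_filter.add((mir, gene))
    deltaz = (
        corr_change.deltaz_records(mirs, genes, network, edge_filter=edge_filter, clamp=True)
        if edge_filter
        else []
    )
    stage("done")
    return ConditionBundle(
        name=config.name,
        enrichments=enrichments,
        de_mirs=de_mirs,
        profile=profile,
        significance=significance,
        deltaz=deltaz,
        config_hash=config.config_hash(),
        seed=config.seed,
    )


def run_condition(config: RunConfig, outdir: str | Path | None = None) -> ConditionBundle:
    """Load the configured input files, run one condition, optionally write
    the five stage tables (every output carries the config hash)."""
    config.validate_paths()
    genes = data_io.read_expression(config.gene_matrix, config.phenotype)
    mirs = data_io.read_expression(config.mir_matrix, config.phenotype)
    network = data_io.read_interactions(config.interactions)
    pathways = data_io.read_gmt(config.pathways)
    bundle = analyze_condition(genes, mirs, network, pathways, config)
    if outdir is not None:
        write_condition(bundle, outdir)
    return bundle


def write_condition(bundle: ConditionBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": bundle.config_hash, "seed": str(bundle.seed), "condition": bundle.name}
    data_io.write_table(bundle.enrichment_frame(), outdir / "pathway_enrichment.tsv", meta)
    data_io.write_table(bundle.de_mir_frame(), outdir / "de_mirs.tsv", meta)
    counts = bundle.profile.counts.reset_index(names="pathway")
    data_io.write_table(counts, outdir / "leg_counts.tsv", meta)
    zs = bundle.profile.zscores.reset_index(names="pathway")
    data_io.write_table(zs, outdir / "leg_zscores.tsv", meta)
    data_io.write_table(bundle.significance.table, outdir / "im_pairs.tsv", meta)
    dz = corr_change.records_to_frame(bundle.deltaz)
    if dz.empty:
        dz = pd.DataFrame(columns=["mir", "gene", "r_d", "r_c", "n_d", "n_c", "delta_z", "regime"])
    data_io.write_table(dz, outdir / "deltaz.tsv", meta)


@dataclass
class MultiConditionResult:
    overlap: downstream.OverlapSummary
    oim: set[str]
    clusters: dict[str, downstream.ClusterResult] = field(default_factory=dict)
    binary_matrices: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_multi(bundles: list[ConditionBundle], n_clusters: int = 2) -> MultiConditionResult:
    """Cross-condition comparison: OIM set, shared pathways/pairs, and a
    Ward-clustered OIM x differentially-expressed-pathway binary matrix per
    condition.

    Conditions whose candidate miR universes are disjoint still intersect
    formally (a warning is logged); the OIM set lives on the shared
    universe by construction.
    """
    if len(bundles) < 2:
        raise ValueError("need >= 2 conditions")
    universes = [set(b.profile.mirs) for b in bundles]
    shared_universe = set.intersection(*universes)
    if not shared_universe:
        logger.warning("run_multi: conditions have disjoint miR universes")
    im_sets = {b.name: b.ims for b in bundles}
    pair_sets = {b.name: b.significant_pairs for b in bundles}
    pathway_sets = {b.name: b.significant_pathways for b in bundles}
    overlap = downstream.overlap_summary(im_sets, pair_sets, pathway_sets)

    clusters: dict[str, downstream.ClusterResult] = {}
    matrices: dict[str, pd.DataFrame] = {}
    for b in bundles:
        rows = sorted(overlap.oim)
        cols = sorted(b.de_pathways & b.significant_pathways)
        if len(rows) < 2 or len(cols) < 2:
            continue
        pairs = b.significant_pairs
        mat = pd.DataFrame(
            [[1.0 if (m, p) in pairs else 0.0 for p in cols] for m in rows],
            index=rows,
            columns=cols,
        )
        # drop empty rows/cols: miRs with no link into these pathways carry
        # no clustering signal
        mat = mat.loc[mat.sum(axis=1) > 0, mat.sum(axis=0) > 0]
        if mat.shape[0] >= 2 and mat.shape[1] >= 2:
            clusters[b.name] = downstream.ward_cluster_binary(mat, n_clusters=n_clusters)
            matrices[b.name] = mat
    return MultiConditionResult(
        overlap=overlap, oim=overlap.oim, clusters=clusters, binary_matrices=matrices
    )
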