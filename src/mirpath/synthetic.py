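"""Synthetic matched gene/miR cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
disease/control cohort in which some pathways are coherently shifted
("dysregulated"), a miR->gene interaction network in which a few planted
important miRs preferentially target the shifted genes of those pathways,
and a subset of planted edges whose miR-gene expression correlation exists
in only one phenotype class (a gain or a loss of correlation in disease).

Expression is Gaussian on a log-like scale — the simplest model under which
the downstream t-test / Pearson-correlation machinery is exact. The
generator makes no attempt to mimic platform noise, batch effects, or miR
family seed-sequence structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CONTROL,
    DISEASE,
    AnnotationList,
    ExpressionDataset,
    GeneSetCollection,
    InteractionNetwork,
    write_expression,
    write_gmt,
    write_interactions,
)

#: evidence codes stamped on every synthetic edge so the >=2-source loader
#: filter is exercised but never rejects a planted edge
SYNTHETIC_SOURCES = frozenset({"S1", "S2"})

GAIN = "gain"
LOSS = "loss"


@dataclass
class SyntheticConfig:
    """Study conditions for a generated cohort.

    Defaults are sized for a seconds-scale run that is still large enough
    for stable enrichment statistics: 300 genes, 60 miRs, 40 pathways of
    10-25 genes, and 20 disease + 20 control samples.
    """

    n_genes: int = 300
    n_mirs: int = 60
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 25)
    n_disease: int = 20
    n_control: int = 20
    frac_dysregulated_pathways: float = 0.1
    effect_size: float = 2.0  # mean shift (delta) of dysregulated genes in disease
    n_planted_im: int = 5
    targets_per_mir: int = 30
    corr_strength: float = 3.0  # regression slope (beta) of coupled gene on miR
    noise_sd: float = 1.0  # residual sd (sigma)
    frac_preferential: float = 0.8  # planted-IM targets drawn from shifted genes
    n_coupled_per_mir: int = 4  # planted correlation-change edges per planted miR
    repression: bool = False  # couple with negative slope (miR up -> gene down)
    seed: int = 0

    def validate(self) -> None:
        if self.n_disease < 4 or self.n_control < 4:
            raise ValueError("need >=4 samples per class (Fisher transform requires N-3 > 0)")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("pathway sizes must satisfy 1 <= lo <= hi <= n_genes")
        if not 0.0 <= self.frac_dysregulated_pathways <= 1.0:
            raise ValueError("frac_dysregulated_pathways must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted_im > self.n_mirs:
            raise ValueError("n_planted_im cannot exceed n_mirs")
        if self.targets_per_mir > self.n_genes:
            raise ValueError("targets_per_mir cannot exceed n_genes")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    dysregulated_pathways: dict[str, str]  # pathway -> "up" | "down"
    planted_ims: frozenset[str]
    planted_edges: frozenset[tuple[str, str, str]]  # (mir, gene, "gain"|"loss")
    shifted_genes: dict[str, str] = field(default_factory=dict)  # gene -> direction

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dysregulated_pathways": self.dysregulated_pathways,
            "planted_ims": sorted(self.planted_ims),
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "shifted_genes": self.shifted_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            dysregulated_pathways=d["dysregulated_pathways"],
            planted_ims=frozenset(d["planted_ims"]),
            planted_edges=frozenset(tuple(e) for e in d["planted_edges"]),
            shifted_genes=d["shifted_genes"],
        )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, InteractionNetwork, GeneSetCollection, SyntheticTruth]:
    """Generate a matched (genes, mirs, network, pathways, truth) bundle.

    Construction order: pathway membership, choice of dysregulated pathways
    (alternating up/down), baseline Gaussian expression, disease mean shifts
    for dysregulated-pathway genes, interaction edges (planted miRs sample
    their targets preferentially from shifted genes), then per-edge
    correlation coupling. A coupled gene's values in the coupling class are
    rewritten as ``class_mean + beta * (mir - mean(mir)) + noise`` so class
    means (hence differential expression) are preserved while the within-
    class correlation is planted. Loss edges are coupled in control only,
    gain edges in disease only. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    mir_ids = [f"mir-{i:03d}" for i in range(1, config.n_mirs + 1)]
    pathway_ids = [f"PW{i:03d}" for i in range(1, config.n_pathways + 1)]
    sample_ids = [f"D{i:03d}" for i in range(1, config.n_disease + 1)] + [
        f"C{i:03d}" for i in range(1, config.n_control + 1)
    ]
    phenotype = pd.Series(
        [DISEASE] * config.n_disease + [CONTROL] * config.n_control, index=sample_ids
    )
    disease_mask = (phenotype == DISEASE).to_numpy()

    # pathway membership: independent draws, overlaps allowed as in curated
    # pathway databases
    lo, hi = config.pathway_size_range
    sets: dict[str, list[str]] = {}
    for pw in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.n_genes, size=size, replace=False)
        sets[pw] = [gene_ids[i] for i in sorted(members)]
    pathways = GeneSetCollection(sets=sets)

    n_dys = int(round(config.frac_dysregulated_pathways * config.n_pathways))
    dys_idx = rng.choice(config.n_pathways, size=n_dys, replace=False) if n_dys else np.array([], dtype=int)
    dysregulated = {
        pathway_ids[int(i)]: ("up" if j % 2 == 0 else "down") for j, i in enumerate(sorted(dys_idx))
    }

    # first dysregulated pathway a gene appears in fixes its direction
    shifted_genes: dict[str, str] = {}
    for pw, direction in dysregulated.items():
        for g in sets[pw]:
            shifted_genes.setdefault(g, direction)

    # baseline expression
    gene_mu = rng.uniform(4.0, 10.0, size=config.n_genes)
    gexpr = gene_mu[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(sample_ids)))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for g, direction in shifted_genes.items():
        sign = 1.0 if direction == "up" else -1.0
        gexpr[gene_pos[g], disease_mask] += sign * config.effect_size

    mir_mu = rng.uniform(4.0, 10.0, size=config.n_mirs)
    mexpr = mir_mu[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_mirs, len(sample_ids)))

    # interaction network; each planted miR is assigned a direction and
    # preferentially targets shifted genes of dysregulated pathways of that
    # direction, so its targeting profile tracks the enrichment signal of a
    # coherent group of pathways
    planted_idx = rng.choice(config.n_mirs, size=config.n_planted_im, replace=False)
    planted_ims = frozenset(mir_ids[int(i)] for i in planted_idx)
    pools = {
        d: [g for g in gene_ids if shifted_genes.get(g) == d] for d in ("up", "down")
    }
    edges: dict[tuple[str, str], frozenset[str]] = {}
    targets: dict[str, list[str]] = {}
    mir_direction: dict[str, str] = {
        m: ("up" if j % 2 == 0 else "down") for j, m in enumerate(sorted(planted_ims))
    }
    for m in mir_ids:
        pool = pools.get(mir_direction.get(m, ""), [])
        if m in planted_ims and not pool:  # no pathway of that direction planted
            pool = [g for g in gene_ids if g in shifted_genes]
        if m in planted_ims and pool:
            n_pref = min(
                int(round(config.frac_preferential * config.targets_per_mir)), len(pool)
            )
            pref = rng.choice(len(pool), size=n_pref, replace=False)
            chosen = {pool[int(i)] for i in pref}
            rest_pool = [g for g in gene_ids if g not in chosen]
            n_rest = config.targets_per_mir - len(chosen)
            rest = rng.choice(len(rest_pool), size=n_rest, replace=False)
            chosen |= {rest_pool[int(i)] for i in rest}
        else:
            idx = rng.choice(config.n_genes, size=config.targets_per_mir, replace=False)
            chosen = {gene_ids[int(i)] for i in idx}
        targets[m] = sorted(chosen)
        for g in targets[m]:
            edges[(m, g)] = SYNTHETIC_SOURCES

    # correlation coupling on planted-IM edges into shifted genes; one
    # coupling per gene so each planted correlation stays clean
    coupled_genes: set[str] = set()
    planted_edges: set[tuple[str, str, str]] = set()
    slope = -config.corr_strength if config.repression else config.corr_strength
    mir_pos = {m: i for i, m in enumerate(mir_ids)}
    for j, m in enumerate(sorted(planted_ims)):
        n_coupled = 0
        for g in targets[m]:
            if g not in shifted_genes or g in coupled_genes or n_coupled >= config.n_coupled_per_mir:
                continue
            regime = GAIN if (len(planted_edges) % 2 == 0) else LOSS
            mask = disease_mask if regime == GAIN else ~disease_mask
            mvec = mexpr[mir_pos[m], mask]
            base_mean = float(gexpr[gene_pos[g], mask].mean())
            gexpr[gene_pos[g], mask] = (
                base_mean
                + slope * (mvec - mvec.mean())
                + rng.normal(0.0, config.noise_sd, size=mask.sum())
            )
            coupled_genes.add(g)
            planted_edges.add((m, g, regime))
            n_coupled += 1

    genes = ExpressionDataset(
        values=pd.DataFrame(gexpr, index=gene_ids, columns=sample_ids), phenotype=phenotype
    )
    mirs = ExpressionDataset(
        values=pd.DataFrame(mexpr, index=mir_ids, columns=sample_ids), phenotype=phenotype.copy()
    )
    network = InteractionNetwork(edges=edges)
    truth = SyntheticTruth(
        dysregulated_pathways=dysregulated,
        planted_ims=planted_ims,
        planted_edges=frozenset(planted_edges),
        shifted_genes=shifted_genes,
    )
    return genes, mirs, network, pathways, truth


def generate_annotation(
    truth: SyntheticTruth,
    contamination: float,
    universe: list[str],
    seed: int = 0,
    name: str = "synthetic_cancer_mirs",
) -> AnnotationList:
    """A synthetic stand-in for a literature-curated miR list.

    Starts from the planted important miRs and replaces a ``contamination``
    fraction with uniform draws from the full miR universe, preserving the
    list size. At contamination 1 the list is a uniform random subset of the
    universe of the same size.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = sorted(truth.planted_ims)
    n_replace = int(round(contamination * len(planted)))
    keep_idx = rng.choice(len(planted), size=len(planted) - n_replace, replace=False)
    kept = {planted[int(i)] for i in keep_idx}
    pool = [m for m in universe if m not in kept]
    add_idx = rng.choice(len(pool), size=n_replace, replace=False)
    members = kept | {pool[int(i)] for i in add_idx}
    return AnnotationList(name=name, members=frozenset(members))


def write_cohort(
    outdir: str | Path,
    genes: ExpressionDataset,
    mirs: ExpressionDataset,
    network: InteractionNetwork,
    pathways: GeneSetCollection,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write a cohort in exactly the file formats the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_matrix": outdir / "genes.tsv",
        "mir_matrix": outdir / "mirs.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "interactions": outdir / "interactions.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression(genes, paths["gene_matrix"], paths["phenotype"])
    mirs.values.to_csv(paths["mir_matrix"], sep="\t", index_label="feature")
    write_interactions(network, paths["interactions"])
    write_gmt(pathways, paths["pathways"])
    truth.to_json(paths["truth"])
    return paths
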