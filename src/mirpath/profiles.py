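"""Pathway x miR leading-edge-targeting profiles.

Each pathway is represented by a profile over miRs: the number of its
leading-edge genes a given miR targets. Per miR, the counts are normalized
to Z-scores across pathways; this Z-profile matrix is the feature matrix
for the random-forest regression of pathway enrichment scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import InteractionNetwork
from .gsea import PathwayEnrichment

logger = logging.getLogger(__name__)


@dataclass
class MiRProfileMatrix:
    """Counts c[pathway, mir] of targeted leading-edge genes, and their
    per-miR Z-normalization z[pathway, mir] (columns standardized across
    pathways with sample sd, ddof=1)."""

    counts: pd.DataFrame  # pathways x miRs, non-negative integers
    zscores: pd.DataFrame | None = None

    @property
    def pathways(self) -> list[str]:
        return list(self.counts.index)

    @property
    def mirs(self) -> list[str]:
        return list(self.counts.columns)


def leg_count_matrix(
    enrichments: list[PathwayEnrichment], network: InteractionNetwork
) -> MiRProfileMatrix:
    """Count, per (pathway, miR), the pathway's leading-edge genes the miR
    targets.

    Pathways with an empty leading edge are excluded (logged); miRs that
    target no leading-edge gene of any retained pathway are dropped
    (logged) — downstream percentages are relative to miRs that interact
    with leading-edge genes at all.
    """
    kept = [e for e in enrichments if e.leading_edge]
    n_empty = len(enrichments) - len(kept)
    if n_empty:
        logger.info("leg_count_matrix: excluded %d pathways with empty leading edge", n_empty)
    if len(kept) < 2:
        raise ValueError("need leading-edge genes for >=2 pathways")
    targets = network.targets_by_mir()
    mirs = sorted(targets)
    counts = np.zeros((len(kept), len(mirs)), dtype=int)
    for i, enr in enumerate(kept):
        leg = set(enr.leading_edge)
        for j, m in enumerate(mirs):
            counts[i, j] = len(targets[m] & leg)
    df = pd.DataFrame(counts, index=[e.pathway_name for e in kept], columns=mirs)
    nonzero = df.columns[(df != 0).any(axis=0)]
    n_dropped = len(df.columns) - len(nonzero)
    if n_dropped:
        logger.info("leg_count_matrix: dropped %d miRs with no leading-edge targets", n_dropped)
    df = df[nonzero]
    if df.shape[1] == 0:
        raise ValueError("no miR targets any leading-edge gene")
    return MiRProfileMatrix(counts=df)


def zscore_profiles(matrix: MiRProfileMatrix) -> MiRProfileMatrix:
    """Standardize each miR's count profile across pathways (ddof=1).

    Constant columns carry no across-pathway signal and cannot be
    normalized; they are dropped with a log message.
    """
    c = matrix.counts
    if len(c.index) < 2:
        raise ValueError("need >=2 pathways to standardize profiles")
    sd = c.std(axis=0, ddof=1)
    keep = sd[sd > 0].index
    n_const = c.shape[1] - len(keep)
    if n_const:
        logger.info("zscore_profiles: dropped %d constant miR columns", n_const)
    if len(keep) == 0:
        raise ValueError("all miR profiles are constant")
    c = c[keep]
    z = (c - c.mean(axis=0)) / c.std(axis=0, ddof=1)
    return MiRProfileMatrix(counts=c, zscores=z)
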