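"""Differential miR-gene expression correlation between disease and control.

For every interaction edge, Pearson correlations are computed separately in
disease (r_D) and control (r_C) samples, Fisher-transformed, and compared:

    dZ = (atanh(r_D) - atanh(r_C)) / sqrt(1/(N_D - 3) + 1/(N_C - 3))

the standard two-sample comparison of correlation coefficients. A positive
dZ is a gain of correlation in disease, a negative one a loss; under no
correlation change dZ is approximately standard normal, so |dZ| > 1 marks
edges whose coupling shifts by more than one null standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, InteractionNetwork

logger = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"

#: |r| clamp window applied just inside +-1 when clamping is enabled
_CLAMP = 1.0 - 1e-7


@dataclass
class DeltaZRecord:
    mir_id: str
    gene_id: str
    r_d: float
    r_c: float
    n_d: int
    n_c: int
    delta_z: float

    @property
    def regime(self) -> str | None:
        if self.delta_z > 0:
            return GAIN
        if self.delta_z < 0:
            return LOSS
        return None


def delta_z(r_d: float, r_c: float, n_d: int, n_c: int, clamp: bool = False) -> float:
    """Standardized difference of Fisher-transformed correlations.

    Both classes need at least four samples (the transform variance is
    1/(N-3)). A correlation of exactly +-1 is an error unless ``clamp`` is
    set, in which case it is pulled just inside the open interval.
    """
    if n_d < 4 or n_c < 4:
        raise ValueError("need N >= 4 in both classes")
    for r in (r_d, r_c):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    if clamp:
        r_d = float(np.clip(r_d, -_CLAMP, _CLAMP))
        r_c = float(np.clip(r_c, -_CLAMP, _CLAMP))
    elif abs(r_d) == 1.0 or abs(r_c) == 1.0:
        raise ValueError("correlation of +-1 has infinite Fisher transform (enable clamp)")
    se = math.sqrt(1.0 / (n_d - 3) + 1.0 / (n_c - 3))
    return (math.atanh(r_d) - math.atanh(r_c)) / se


def edge_correlations(
    mirs: ExpressionDataset,
    genes: ExpressionDataset,
    network: InteractionNetwork,
    edge_filter: set[tuple[str, str]] | None = None,
) -> list[tuple[tuple[str, str], float, float]]:
    """Pearson r of each interacting (miR, gene) pair per phenotype class.

    ``edge_filter`` optionally restricts to a subset of edges (e.g. those
    touching leading-edge genes of selected pathways). Edges with an
    unmeasured miR or gene, or with zero within-class variance, are skipped
    and logged.
    """
    if list(mirs.sample_ids) != list(genes.sample_ids):
        raise ValueError("miR and gene datasets must share aligned sample ids")
    if not mirs.phenotype.equals(genes.phenotype):
        raise ValueError("miR and gene datasets must share the phenotype")
    disease, control = genes.class_masks()
    if disease.sum() < 4 or control.sum() < 4:
        raise ValueError("need >= 4 samples per class for correlation change")
    gvals = genes.values
    mvals = mirs.values
    edges = network.edges.keys() if edge_filter is None else edge_filter
    out: list[tuple[tuple[str, str], float, float]] = []
    n_skipped = 0
    for mir, gene in edges:
        if mir not in mvals.index or gene not in gvals.index:
            n_skipped += 1
            continue
        x = mvals.loc[mir].to_numpy(dtype=float)
        y = gvals.loc[gene].to_numpy(dtype=float)
        rs = []
        degenerate = False
        for mask in (disease, control):
            xm, ym = x[mask], y[mask]
            if xm.std() == 0 or ym.std() == 0:
                degenerate = True
                break
            rs.append(float(np.corrcoef(xm, ym)[0, 1]))
        if degenerate:
            n_skipped += 1
            continue
        out.append(((mir, gene), rs[0], rs[1]))
    if n_skipped:
        logger.info("edge_correlations: skipped %d unmeasured/degenerate edges", n_skipped)
    return out


def deltaz_records(
    mirs: ExpressionDataset,
    genes: ExpressionDataset,
    network: InteractionNetwork,
    edge_filter: set[tuple[str, str]] | None = None,
    clamp: bool = True,
) -> list[DeltaZRecord]:
    """Full dZ computation over (optionally filtered) network edges."""
    n_d = int((genes.phenotype == "disease").sum())
    n_c = int((genes.phenotype == "control").sum())
    records = []
    for (mir, gene), r_d, r_c in edge_correlations(mirs, genes, network, edge_filter):
        records.append(
            DeltaZRecord(
                mir_id=mir,
                gene_id=gene,
                r_d=r_d,
                r_c=r_c,
                n_d=n_d,
                n_c=n_c,
                delta_z=delta_z(r_d, r_c, n_d, n_c, clamp=clamp),
            )
        )
    return records


def deltaz_map(
    records: list[DeltaZRecord], threshold: float = 1.0, bins: int = 40
) -> tuple[list[DeltaZRecord], tuple[np.ndarray, np.ndarray]]:
    """Edges with |dZ| above ``threshold`` plus a histogram of all dZ values.

    The retained edges are the candidate gain/loss interaction map; the
    histogram supports inspection of the multimodality of correlation
    changes.
    """
    if not records:
        raise ValueError("no correlation-change records")
    values = np.array([r.delta_z for r in records])
    hist = np.histogram(values, bins=bins)
    kept = [r for r in records if abs(r.delta_z) > threshold]
    return kept, hist


def records_to_frame(records: list[DeltaZRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.mir_id, r.gene_id, r.r_d, r.r_c, r.n_d, r.n_c, r.delta_z, r.regime or "none")
            for r in records
        ],
        columns=["mir", "gene", "r_d", "r_c", "n_d", "n_c", "delta_z", "regime"],
    )
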