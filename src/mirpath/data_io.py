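"""Readers and writers for expression matrices, gene sets, interaction networks and result tables.

All identifiers are treated as case-sensitive opaque strings. The interaction
loader enforces the evidence filter (an edge must be reported by at least two
sources) at load time, which is the network-quality rule the whole analysis
rests on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"

#: accepted spellings in phenotype files, mapped to the canonical labels
_PHENOTYPE_ALIASES = {
    "disease": DISEASE,
    "tumor": DISEASE,
    "cancer": DISEASE,
    "case": DISEASE,
    "control": CONTROL,
    "normal": CONTROL,
}


class ParseError(ValueError):
    """Raised when an input file violates its expected layout."""


@dataclass
class ExpressionDataset:
    """A features x samples expression matrix with a binary phenotype.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression values on a log-like scale, rows indexed by feature id,
        columns by sample id.
    phenotype : pandas.Series
        Per-sample label, ``"disease"`` or ``"control"``, indexed and ordered
        like the matrix columns.
    """

    values: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if list(self.phenotype.index) != list(self.values.columns):
            raise ValueError("phenotype index must match sample columns")
        bad = set(self.phenotype) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        for cls in (DISEASE, CONTROL):
            if int((self.phenotype == cls).sum()) < 2:
                raise ValueError(f"need >=2 {cls} samples")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_disease(self) -> int:
        return int((self.phenotype == DISEASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.phenotype == CONTROL).sum())

    def class_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (disease, control) over the sample axis."""
        ph = self.phenotype.to_numpy()
        return ph == DISEASE, ph == CONTROL

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class InteractionNetwork:
    """miR -> gene edges with per-edge evidence-source sets."""

    edges: dict[tuple[str, str], frozenset[str]]
    n_discarded: int = 0

    @property
    def mir_ids(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def gene_ids(self) -> set[str]:
        return {g for _, g in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, mir_id: str) -> set[str]:
        return {g for (m, g) in self.edges if m == mir_id}

    def targets_by_mir(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for m, g in self.edges:
            out.setdefault(m, set()).add(g)
        return out


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (ordered, unique genes per set)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class AnnotationList:
    """A named set of miR ids (e.g. literature cancer miRs)."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...).

    Duplicate genes within a line are dropped keeping the first occurrence;
    a duplicate set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen: list[str] = []
            for g in genes:
                if g and g not in seen:
                    seen.append(g)
            if not seen:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = seen
            descriptions[name] = desc
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_expression(matrix_path: str | Path, phenotype_path: str | Path) -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus a 2-column phenotype TSV.

    The matrix has a header row of sample ids and one feature per row. Rows
    containing any missing value ("", NA, NaN, null) are dropped with a
    logged count. Every sample in the matrix must appear in the phenotype
    file, and both classes need at least two samples.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA", "NaN", "null", ""])
    if not mat.index.is_unique:
        raise ParseError(f"{matrix_path}: duplicate feature ids")
    n_before = len(mat)
    mat = mat.dropna(axis=0, how="any")
    n_dropped = n_before - len(mat)
    if n_dropped:
        logger.info("read_expression: dropped %d feature rows with missing values", n_dropped)
    if mat.empty:
        raise ParseError(f"{matrix_path}: no complete feature rows")

    pheno_raw = pd.read_csv(phenotype_path, sep="\t", header=None, dtype=str)
    if pheno_raw.shape[1] < 2:
        raise ParseError(f"{phenotype_path}: expected 2 tab-separated columns")
    labels: dict[str, str] = {}
    for _, (sid, cls) in pheno_raw.iloc[:, :2].iterrows():
        key = str(cls).strip().lower()
        if key not in _PHENOTYPE_ALIASES:
            raise ParseError(f"{phenotype_path}: unknown class label {cls!r} for sample {sid!r}")
        labels[str(sid)] = _PHENOTYPE_ALIASES[key]

    missing = [s for s in mat.columns if s not in labels]
    if missing:
        raise ParseError(f"{phenotype_path}: samples without phenotype: {missing[:5]}")
    phenotype = pd.Series([labels[s] for s in mat.columns], index=mat.columns)
    for cls in (DISEASE, CONTROL):
        if int((phenotype == cls).sum()) < 2:
            raise ParseError(f"need >=2 {cls} samples, got {int((phenotype == cls).sum())}")
    return ExpressionDataset(values=mat.astype(float), phenotype=phenotype)


def read_interactions(path: str | Path, min_sources: int = 2) -> InteractionNetwork:
    """Read a miR->gene edge list TSV (mir, gene, comma-separated sources).

    Duplicate (mir, gene) lines merge their source sets before filtering.
    Edges supported by fewer than ``min_sources`` evidence sources are
    discarded; the returned network records how many were dropped.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields (mir, gene, sources)")
            mir, gene, src_field = fields[0], fields[1], fields[2]
            sources = {s.strip() for s in src_field.split(",") if s.strip()}
            if not sources:
                raise ParseError(f"{path}: line {lineno}: empty source field")
            n_lines += 1
            merged.setdefault((mir, gene), set()).update(sources)
    if n_lines == 0:
        raise ParseError(f"{path}: empty interaction file")
    kept = {k: frozenset(v) for k, v in merged.items() if len(v) >= min_sources}
    n_discarded = len(merged) - len(kept)
    logger.info(
        "read_interactions: retained %d edges, discarded %d with <%d sources",
        len(kept), n_discarded, min_sources,
    )
    return InteractionNetwork(edges=kept, n_discarded=n_discarded)


def read_annotation(path: str | Path, name: str | None = None) -> AnnotationList:
    """Read a one-id-per-line annotation list of miR ids."""
    members: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                members.add(line.split("\t")[0])
    return AnnotationList(name=name or Path(path).stem, members=frozenset(members))


def write_table(records: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None) -> None:
    """Write a result table as TSV with a header row.

    Floats are rendered at 6 significant digits. Optional metadata key-value
    pairs are written as leading ``#`` comment lines so stage outputs can
    carry the run's configuration hash.
    """
    if list(records.columns) == []:
        raise ValueError("records must have a column schema")
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        records.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (skipping # comments)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_interactions(network: InteractionNetwork, path: str | Path) -> None:
    """Write an interaction network in the 3-column edge TSV dialect."""
    rows = sorted((m, g, ",".join(sorted(src))) for (m, g), src in network.edges.items())
    with open(path, "w") as fh:
        for m, g, s in rows:
            fh.write(f"{m}\t{g}\t{s}\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(genes) + "\n")


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path, phenotype_path: str | Path) -> None:
    dataset.values.to_csv(matrix_path, sep="\t", index_label="feature")
    with open(phenotype_path, "w") as fh:
        for sid, cls in dataset.phenotype.items():
            fh.write(f"{sid}\t{cls}\n")
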