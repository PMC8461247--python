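"""Readers, writers and validators for the external tables.

All inputs are plain TSV: per-omics numeric matrices (rows = features,
columns = sample IDs), a gene annotation (BED-like or TSV), a methylation
probe manifest, a miRNA-to-target-gene map, and a sample label table.
Genomic coordinates are 1-based inclusive in all on-disk tables and are
converted to 0-based half-open windows internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens accepted as "missing" in numeric matrix cells (besides empty cells).
MISSING_TOKENS = ("NA", "NaN", "nan", "null", "")


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level annotation: position of the transcription start site.

    ``tss`` is the 1-based genomic coordinate of the transcription start
    site; ``strand`` is '+' or '-'. The promoter window used for probe
    aggregation extends upstream of the TSS in the strand-aware sense.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TableFormatError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 1:
            raise TableFormatError(f"gene {self.gene_id}: tss must be >= 1")


@dataclass
class OmicsMatrix:
    """One omics layer as a feature x sample numeric matrix.

    ``values`` has shape (len(gene_ids), len(sample_ids)).  NaN encodes a
    missing measurement; downstream preprocessing is responsible for
    removing or imputing missingness before tensor assembly.
    """

    omics_name: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"{self.omics_name}: value shape {self.values.shape} does not match "
                f"axis labels ({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise TableFormatError(f"{self.omics_name}: duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError(f"{self.omics_name}: duplicate sample IDs")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omics_name: str) -> "OmicsMatrix":
        return cls(
            omics_name=omics_name,
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsMatrix(
            omics_name=self.omics_name,
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "OmicsMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return OmicsMatrix(
            omics_name=self.omics_name,
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
        )


@dataclass
class LabelTable:
    """Categorical label per sample (e.g., molecular subtype)."""

    labels: dict[str, str]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.labels.values():
            out[v] = out.get(v, 0) + 1
        return out

    def vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without a label: {missing[:5]}")
        return np.asarray([self.labels[s] for s in sample_ids], dtype=object)


@dataclass(frozen=True)
class AttributeVerdict:
    """Outcome of the categorical-attribute usability filter."""

    accepted: bool
    reason: str
    n_classes: int
    min_class_fraction: float


def _parse_numeric(cell: str, row: str, col: str, path: str) -> float:
    s = cell.strip()
    if s in MISSING_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise TableFormatError(
            f"{path}: non-numeric cell {cell!r} at row {row!r}, column {col!r}"
        ) from None


def read_matrix(path: str | Path, kind: str = "expression") -> OmicsMatrix:
    """Read a feature x sample TSV matrix.

    The first column holds feature IDs, the header row holds sample IDs.
    Empty cells and :data:`MISSING_TOKENS` parse to NaN.  Duplicate
    feature or sample IDs and non-numeric cells are hard errors.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if frame.index.has_duplicates:
        dups = sorted(frame.index[frame.index.duplicated()].unique())
        raise TableFormatError(f"{path}: duplicate feature IDs: {dups[:5]}")
    if frame.columns.has_duplicates:
        raise TableFormatError(f"{path}: duplicate sample IDs in header")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        column = frame.iloc[:, j]
        for i, (row_id, cell) in enumerate(column.items()):
            values[i, j] = _parse_numeric(str(cell), str(row_id), str(col), str(path))
    return OmicsMatrix(
        omics_name=kind,
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=values,
    )


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; NaN is written as 'NA'."""
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation from a 6-column BED or a headered TSV.

    BED layout: chrom, start, end, gene_id, biotype, strand (0-based
    half-open); the TSS is ``start + 1`` on '+' and ``end`` on '-'.
    TSV layout requires columns gene_id, chrom, strand, tss, biotype
    with 1-based TSS.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].split("\t")
    annotations: dict[str, GeneAnnotation] = {}
    if first[0] == "gene_id":  # headered TSV
        table = pd.read_csv(path, sep="\t", dtype=str)
        for row in table.itertuples(index=False):
            ann = GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                biotype=str(row.biotype),
            )
            if ann.gene_id in annotations:
                raise TableFormatError(f"{path}: duplicate gene {ann.gene_id}")
            annotations[ann.gene_id] = ann
    else:  # BED6-like
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id", "biotype", "strand"],
            dtype=str,
        )
        for row in table.itertuples(index=False):
            strand = str(row.strand)
            tss = int(row.start) + 1 if strand == "+" else int(row.end)
            ann = GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=strand,
                tss=tss,
                biotype=str(row.biotype),
            )
            if ann.gene_id in annotations:
                raise TableFormatError(f"{path}: duplicate gene {ann.gene_id}")
            annotations[ann.gene_id] = ann
    return annotations


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest TSV with columns probe_id, chrom, pos (1-based)."""
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": int})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(table.columns):
        raise TableFormatError(f"{path}: manifest needs columns {sorted(required)}")
    if table["probe_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate probe IDs")
    if (table["pos"] < 1).any():
        raise TableFormatError(f"{path}: probe positions must be >= 1")
    return table.set_index("probe_id")


def read_mirna_targets(path: str | Path) -> dict[str, set[str]]:
    """Read a miRNA target map: one (mirna_id, gene_id) pair per line.

    miRNAs with empty target sets are never produced by construction.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"}.issubset(table.columns):
        raise TableFormatError(f"{path}: target map needs columns mirna_id, gene_id")
    out: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(str(row.mirna_id), set()).add(str(row.gene_id))
    return out


def read_labels(path: str | Path) -> LabelTable:
    """Read a sample label TSV with columns sample_id, label."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "label"}.issubset(table.columns):
        raise TableFormatError(f"{path}: label table needs columns sample_id, label")
    if table["sample_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample IDs in label table")
    return LabelTable(labels=dict(zip(table["sample_id"], table["label"])))


def write_labels(labels: LabelTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.labels), "label": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def match_samples(tables: Sequence[OmicsMatrix | Sequence[str]]) -> list[str]:
    """Intersect sample IDs across omics tables, in lexicographic order.

    Only samples measured in every layer can enter the tensor; the number
    dropped from each layer is logged.  An empty intersection is a hard
    error.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to match samples")
    sample_sets: list[set[str]] = []
    names: list[str] = []
    for i, t in enumerate(tables):
        if isinstance(t, OmicsMatrix):
            sample_sets.append(set(t.sample_ids))
            names.append(t.omics_name)
        else:
            sample_sets.append(set(t))
            names.append(f"table_{i}")
    common = set.intersection(*sample_sets)
    if not common:
        raise ValueError("no samples shared across all omics tables")
    for name, s in zip(names, sample_sets):
        dropped = len(s) - len(common)
        if dropped:
            logger.info("match_samples: %s drops %d unmatched samples", name, dropped)
    return sorted(common)


def filter_label_attribute(
    labels: LabelTable,
    max_classes: int = 5,
    min_class_fraction: float = 0.05,
) -> AttributeVerdict:
    """Decide whether a categorical attribute is usable for supervision.

    Accepted iff ``2 <= n_classes < max_classes`` (the upper bound is
    exclusive) and the smallest class holds at least ``min_class_fraction``
    of the samples (the sample-bias guard).  Returns a verdict with a
    reason rather than raising.
    """
    counts = labels.counts()
    n_classes = len(counts)
    total = sum(counts.values())
    min_frac = min(counts.values()) / total if total else 0.0
    if n_classes < 2:
        return AttributeVerdict(False, f"only {n_classes} class(es)", n_classes, min_frac)
    if n_classes >= max_classes:
        return AttributeVerdict(
            False, f"{n_classes} classes >= max_classes={max_classes}", n_classes, min_frac
        )
    if min_frac < min_class_fraction:
        return AttributeVerdict(
            False,
            f"smallest class holds {min_frac:.3f} < {min_class_fraction} of samples",
            n_classes,
            min_frac,
        )
    return AttributeVerdict(True, "accepted", n_classes, min_frac)
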