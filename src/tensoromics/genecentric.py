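"""Gene-centric transformation of each omics layer and tensor assembly.

Each omics is reduced to a gene x sample matrix sharing a common gene and
sample axis: expression is log2-quantile normalized; methylation probes
are averaged over strand-aware promoter windows; miRNA expression is
aggregated over target-gene bundles.  The normalized matrices are min-max
scaled to [0,1] per omics slice and stacked into a third-order tensor
(genes x samples x omics).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tensoromics.io import GeneAnnotation, OmicsMatrix, write_matrix, read_matrix

logger = logging.getLogger(__name__)


@dataclass
class OmicsTensor:
    """Non-negative third-order array with aligned axis labels.

    ``values`` has shape (n_genes, n_samples, n_omics); every entry lies
    in [0, 1] after per-slice min-max scaling and contains no NaN.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    omics_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.gene_ids), len(self.sample_ids), len(self.omics_names))
        if self.values.shape != expected:
            raise ValueError(
                f"tensor shape {self.values.shape} does not match axis labels {expected}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def slice(self, omics: str | int) -> OmicsMatrix:
        k = omics if isinstance(omics, int) else self.omics_names.index(omics)
        return OmicsMatrix(
            omics_name=self.omics_names[k],
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[:, :, k].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsTensor":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsTensor(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            omics_names=list(self.omics_names),
            values=self.values[:, idx, :],
        )

    def write(self, out_dir: str | Path) -> None:
        """Write the tensor as one TSV per omics slice plus a JSON sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, name in enumerate(self.omics_names):
            write_matrix(self.slice(k), out_dir / f"tensor_{name}.tsv")
        sidecar = {
            "gene_ids": self.gene_ids,
            "sample_ids": self.sample_ids,
            "omics_names": self.omics_names,
            "shape": list(self.shape),
        }
        (out_dir / "tensor.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, in_dir: str | Path) -> "OmicsTensor":
        in_dir = Path(in_dir)
        sidecar = json.loads((in_dir / "tensor.json").read_text())
        slices = []
        for name in sidecar["omics_names"]:
            m = read_matrix(in_dir / f"tensor_{name}.tsv", kind=name)
            slices.append(m.values)
        return cls(
            gene_ids=sidecar["gene_ids"],
            sample_ids=sidecar["sample_ids"],
            omics_names=sidecar["omics_names"],
            values=np.stack(slices, axis=2),
        )


def quantile_normalize(
    values: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise quantile normalization.

    Every column is mapped onto a common reference distribution; by
    default the reference is the across-column mean of the order
    statistics, so afterwards all columns share one multiset of values.
    Ties within a column receive the mean of the reference values over
    the tied rank range.

    Passing a precomputed ``reference`` (e.g., from training samples)
    maps new columns onto it without refitting, which keeps evaluation
    splits leak-free.

    Returns the normalized array and the reference used.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if reference is None:
        reference = np.sort(values, axis=0).mean(axis=1)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (n,):
            raise ValueError(
                f"reference length {reference.shape} does not match row count {n}"
            )
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        sorter = np.argsort(col, kind="stable")
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[sorter[k + 1]] == col[sorter[i]]:
                k += 1
            out[sorter[i : k + 1], j] = reference[i : k + 1].mean()
            i = k + 1
    return out, reference


def log2_quantile_normalize(
    matrix: OmicsMatrix,
    reference: np.ndarray | None = None,
    log: bool = True,
) -> tuple[OmicsMatrix, np.ndarray]:
    """log2(x+1) transform followed by column quantile normalization.

    Requires non-negative input (a pseudocount of 1 absorbs zeros).
    ``log=False`` skips the transform for layers that are already on a
    bounded scale (methylation betas).
    """
    values = matrix.values
    if np.nanmin(values) < 0:
        raise ValueError(f"{matrix.omics_name}: negative values cannot be log-transformed")
    if log:
        values = np.log2(values + 1.0)
    normalized, reference = quantile_normalize(values, reference)
    return (
        OmicsMatrix(
            omics_name=matrix.omics_name,
            gene_ids=list(matrix.gene_ids),
            sample_ids=list(matrix.sample_ids),
            values=normalized,
        ),
        reference,
    )


def promoter_window(ann: GeneAnnotation, window: int = 2000) -> tuple[int, int]:
    """Strand-aware promoter interval in 0-based half-open coordinates.

    On '+' the window covers the 1-based inclusive range
    [TSS - window, TSS]; on '-' it covers [TSS, TSS + window], i.e.,
    always the ``window`` bases upstream of transcription plus the TSS.
    """
    if ann.strand == "+":
        lo, hi = max(1, ann.tss - window), ann.tss
    else:
        lo, hi = ann.tss, ann.tss + window
    return lo - 1, hi  # 0-based half-open


def methylation_to_gene(
    probes: OmicsMatrix,
    manifest: pd.DataFrame,
    annotation: Mapping[str, GeneAnnotation],
    window: int = 2000,
) -> OmicsMatrix:
    """Aggregate probe-level beta values into per-gene promoter methylation.

    Probes missing in all samples are dropped first.  Each gene's value
    per sample is the arithmetic mean of the non-missing betas of the
    probes inside its promoter window; genes with no probe in the window
    are absent from the output.  A per-sample value stays NaN when every
    window probe is missing for that sample.
    """
    finite = probes.values[np.isfinite(probes.values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("methylation betas must lie in [0, 1]")
    keep = ~np.all(np.isnan(probes.values), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("methylation_to_gene: dropped %d all-missing probes", n_dropped)
    probe_ids = [p for p, k in zip(probes.gene_ids, keep) if k]
    values = probes.values[keep, :]

    probe_pos: dict[str, list[tuple[int, int]]] = {}
    for i, pid in enumerate(probe_ids):
        if pid not in manifest.index:
            logger.warning("probe %s absent from manifest; skipped", pid)
            continue
        row = manifest.loc[pid]
        probe_pos.setdefault(str(row["chrom"]), []).append((int(row["pos"]), i))

    gene_rows: list[str] = []
    out_rows: list[np.ndarray] = []
    for gene_id in sorted(annotation):
        ann = annotation[gene_id]
        lo, hi = promoter_window(ann, window)
        hits = [
            i
            for pos, i in probe_pos.get(ann.chrom, [])
            if lo <= (pos - 1) < hi  # manifest pos is 1-based
        ]
        if not hits:
            continue
        with np.errstate(invalid="ignore"):
            row = np.nanmean(values[hits, :], axis=0)
        gene_rows.append(gene_id)
        out_rows.append(row)
    if not gene_rows:
        raise ValueError("no gene has a probe inside its promoter window")
    return OmicsMatrix(
        omics_name="ME",
        gene_ids=gene_rows,
        sample_ids=list(probes.sample_ids),
        values=np.vstack(out_rows),
    )


def mirna_to_gene(
    mirna_matrix: OmicsMatrix,
    target_map: Mapping[str, set[str]],
    mode: str = "geometric",
    gene_ids: Sequence[str] | None = None,
) -> OmicsMatrix:
    """Aggregate miRNA expression per target-gene bundle.

    miRNAs with zero expression in all samples are excluded first.  For
    each gene, the miRNAs targeting it form a bundle; in ``geometric``
    mode the bundle value is exp(mean(ln(x+1))) - 1 per sample (the
    pseudocount keeps zeros finite), in ``arithmetic`` mode the plain
    mean.  Genes not targeted by any miRNA receive 0 in all samples; the
    output covers ``gene_ids`` when given, otherwise all mapped targets.
    """
    if not target_map:
        raise ValueError("empty miRNA target map")
    if mode not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    keep = ~np.all(mirna_matrix.values == 0, axis=1)
    mirna_ids = [m for m, k in zip(mirna_matrix.gene_ids, keep) if k]
    values = mirna_matrix.values[keep, :]
    row_of = {m: i for i, m in enumerate(mirna_ids)}

    bundles: dict[str, list[int]] = {}
    for mirna, targets in target_map.items():
        if mirna not in row_of:
            continue
        for gene in targets:
            bundles.setdefault(gene, []).append(row_of[mirna])

    if gene_ids is None:
        gene_ids = sorted(bundles)
    out = np.zeros((len(gene_ids), values.shape[1]))
    for gi, gene in enumerate(gene_ids):
        rows = bundles.get(gene)
        if not rows:
            continue
        sub = values[rows, :]
        if mode == "geometric":
            out[gi, :] = np.expm1(np.mean(np.log1p(sub), axis=0))
        else:
            out[gi, :] = sub.mean(axis=0)
    return OmicsMatrix(
        omics_name="MI",
        gene_ids=list(gene_ids),
        sample_ids=list(mirna_matrix.sample_ids),
        values=out,
    )


def filter_genes(
    matrices: Sequence[OmicsMatrix],
    annotation: Mapping[str, GeneAnnotation],
    methylation_name: str = "ME",
    max_missing_fraction: float = 0.8,
    biotype: str = "protein_coding",
) -> list[str]:
    """Select the common gene axis for the tensor.

    A gene is kept iff it is annotated with the requested biotype, is
    present in every gene-centric matrix, and its promoter methylation is
    missing in at most ``max_missing_fraction`` of the samples.  The
    result is lexicographically sorted for reproducibility.
    """
    common: set[str] | None = None
    meth = None
    for m in matrices:
        common = set(m.gene_ids) if common is None else common & set(m.gene_ids)
        if m.omics_name == methylation_name:
            meth = m
    if common is None:
        raise ValueError("no matrices given")
    kept: list[str] = []
    for gene in sorted(common):
        ann = annotation.get(gene)
        if ann is None or ann.biotype != biotype:
            continue
        if meth is not None:
            row = meth.values[meth.gene_ids.index(gene), :]
            if np.isnan(row).mean() > max_missing_fraction:
                continue
        kept.append(gene)
    return kept


def minmax_scale_slice(
    matrix: OmicsMatrix, bounds: tuple[float, float] | None = None
) -> tuple[OmicsMatrix, tuple[float, float]]:
    """Scale a whole omics slice into [0, 1] by its global min/max.

    Scaling is global per slice, not per gene, so relative magnitudes
    within the slice survive while the slices become comparable.  A
    constant slice maps to all zeros.  Passing precomputed ``bounds``
    (from training data) applies them and clips into [0, 1].
    """
    values = matrix.values
    if bounds is None:
        lo, hi = float(np.nanmin(values)), float(np.nanmax(values))
    else:
        lo, hi = bounds
    if hi > lo:
        scaled = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    else:
        scaled = np.zeros_like(values)
    return (
        OmicsMatrix(
            omics_name=matrix.omics_name,
            gene_ids=list(matrix.gene_ids),
            sample_ids=list(matrix.sample_ids),
            values=scaled,
        ),
        (lo, hi),
    )


def impute_row_mean(matrix: OmicsMatrix) -> OmicsMatrix:
    """Replace residual NaN by the gene's mean within the slice (0 if all NaN)."""
    values = matrix.values.copy()
    nan_mask = np.isnan(values)
    if nan_mask.any():
        with np.errstate(invalid="ignore"):
            row_means = np.nanmean(np.where(nan_mask, np.nan, values), axis=1)
        row_means = np.nan_to_num(row_means, nan=0.0)
        rows, cols = np.nonzero(nan_mask)
        values[rows, cols] = row_means[rows]
    return OmicsMatrix(
        omics_name=matrix.omics_name,
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=values,
    )


def assemble_tensor(
    matrices: Sequence[OmicsMatrix], scale: bool = True
) -> OmicsTensor:
    """Stack gene-centric omics matrices into a genes x samples x omics tensor.

    All matrices must share identical gene and sample axes.  Residual
    missing values are imputed by the per-gene per-omics mean, then each
    slice is min-max scaled so every tensor entry lies in [0, 1].
    """
    if not matrices:
        raise ValueError("no matrices to assemble")
    first = matrices[0]
    for m in matrices[1:]:
        if m.gene_ids != first.gene_ids or m.sample_ids != first.sample_ids:
            raise ValueError(
                f"axis mismatch between {first.omics_name} and {m.omics_name}"
            )
    slices = []
    for m in matrices:
        m = impute_row_mean(m)
        if scale:
            m, _ = minmax_scale_slice(m)
        slices.append(m.values)
    values = np.stack(slices, axis=2)
    if np.isnan(values).any():
        raise AssertionError("tensor contains NaN after imputation")
    return OmicsTensor(
        gene_ids=list(first.gene_ids),
        sample_ids=list(first.sample_ids),
        omics_names=[m.omics_name for m in matrices],
        values=values,
    )
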