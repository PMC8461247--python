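"""Normalization and tensor-assembly plumbing shared by the CLI and evaluator.

Each omics layer follows its own normalization rule: expression-like
layers (gene expression, aggregated miRNA) are log2(x+1) transformed and
quantile normalized across samples; promoter methylation (already a
bounded beta value) is quantile normalized without the log.  All layers
are then min-max scaled per slice and stacked.

Every step accepts precomputed statistics (quantile reference
distributions, min/max bounds) so that evaluation splits can normalize
held-out samples with training statistics only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from tensoromics.genecentric import (
    OmicsTensor,
    assemble_tensor,
    filter_genes,
    impute_row_mean,
    log2_quantile_normalize,
    methylation_to_gene,
    minmax_scale_slice,
    mirna_to_gene,
)
from tensoromics.io import (
    LabelTable,
    OmicsMatrix,
    match_samples,
    read_annotation,
    read_labels,
    read_matrix,
    read_mirna_targets,
    read_probe_manifest,
)

#: Omics names that skip the log2 transform (bounded beta values).
NO_LOG_OMICS = frozenset({"ME", "methylation"})


def normalize_matrices(
    matrices: Sequence[OmicsMatrix],
    references: Mapping[str, np.ndarray] | None = None,
) -> tuple[list[OmicsMatrix], dict[str, np.ndarray]]:
    """Per-omics normalization, optionally against precomputed references."""
    normalized: list[OmicsMatrix] = []
    refs_out: dict[str, np.ndarray] = {}
    for m in matrices:
        ref = references.get(m.omics_name) if references else None
        out, ref_used = log2_quantile_normalize(
            m, reference=ref, log=m.omics_name not in NO_LOG_OMICS
        )
        normalized.append(out)
        refs_out[m.omics_name] = ref_used
    return normalized, refs_out


def preprocess_and_assemble(
    matrices: Sequence[OmicsMatrix],
    references: Mapping[str, np.ndarray] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[OmicsTensor, dict[str, np.ndarray], dict[str, tuple[float, float]]]:
    """Normalize, impute, scale and stack gene-centric matrices.

    Returns the tensor plus the quantile references and min-max bounds
    actually used, so a second call can reuse them on held-out samples.
    """
    normalized, refs = normalize_matrices(matrices, references)
    scaled: list[OmicsMatrix] = []
    bounds_out: dict[str, tuple[float, float]] = {}
    for m in normalized:
        m = impute_row_mean(m)
        b = bounds.get(m.omics_name) if bounds else None
        m, b_used = minmax_scale_slice(m, bounds=b)
        scaled.append(m)
        bounds_out[m.omics_name] = b_used
    tensor = assemble_tensor(scaled, scale=False)
    return tensor, refs, bounds_out


def load_gene_centric_matrices(
    data_dir: str | Path,
    window: int = 2000,
    mirna_mode: str = "geometric",
    max_missing_fraction: float = 0.8,
) -> tuple[list[OmicsMatrix], LabelTable]:
    """Read a fixture-style directory into aligned gene-centric matrices.

    Expects expression.tsv, methylation_probes.tsv, probe_manifest.tsv,
    mirna.tsv, mirna_targets.tsv, annotation.tsv and labels.tsv.  Samples
    are intersected across layers; methylation probes are aggregated over
    promoter windows; miRNAs over target bundles; the gene axis is the
    filtered common set (protein-coding, methylation coverage).  The
    returned matrices are raw (un-normalized) but axis-aligned.
    """
    data_dir = Path(data_dir)
    expr = read_matrix(data_dir / "expression.tsv", kind="GE")
    probes = read_matrix(data_dir / "methylation_probes.tsv", kind="methylation_probe")
    mirna = read_matrix(data_dir / "mirna.tsv", kind="mirna")
    manifest = read_probe_manifest(data_dir / "probe_manifest.tsv")
    targets = read_mirna_targets(data_dir / "mirna_targets.tsv")
    annotation = read_annotation(data_dir / "annotation.tsv")
    labels = read_labels(data_dir / "labels.tsv")

    samples = match_samples([expr, probes, mirna])
    expr = expr.subset_samples(samples)
    meth = methylation_to_gene(
        probes.subset_samples(samples), manifest, annotation, window=window
    )
    genes = filter_genes([expr, meth], annotation,
                         max_missing_fraction=max_missing_fraction)
    if not genes:
        raise ValueError("no genes survive the common-axis filter")
    mi = mirna_to_gene(
        mirna.subset_samples(samples), targets, mode=mirna_mode, gene_ids=genes
    )
    matrices = [
        expr.subset_genes(genes),
        meth.subset_genes(genes),
        mi,
    ]
    return matrices, labels


def build_tensor_from_files(
    data_dir: str | Path, **kwargs
) -> tuple[OmicsTensor, LabelTable]:
    """End-to-end: fixture directory -> normalized [0,1] tensor + labels."""
    matrices, labels = load_gene_centric_matrices(data_dir, **kwargs)
    tensor, _, _ = preprocess_and_assemble(matrices)
    return tensor, labels
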