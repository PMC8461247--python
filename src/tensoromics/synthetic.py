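"""Synthetic matched multi-omics cohorts with planted CP structure.

The generator emulates the situation the pipeline is built for: a
cohort of samples carrying a categorical phenotype, measured on three
omics layers that share a latent low-rank structure.  Each of the R*
planted rank-1 components is "owned" by one phenotype label — samples
of that label load strongly on it, all others sit near a small
baseline — so the downstream feature selection has a known ground
truth.  Gene factors are sparse (a random 5% support per component) and
the omics factor routes each component's signal across the layers
(uniformly, or concentrated in one layer to emulate, e.g., a
methylation-dominated phenotype).

The tensor is the planted sum plus zero-truncated Gaussian noise,
min-max scaled per omics slice, exactly as real data leave the
preprocessing stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from tensoromics.genecentric import OmicsTensor, minmax_scale_slice
from tensoromics.io import LabelTable, OmicsMatrix, write_labels, write_matrix

logger = logging.getLogger(__name__)

DEFAULT_OMICS = ("GE", "ME", "MI")

#: Scale (in log2 units) used to invert the scaled tensor back to raw counts
#: when writing fixture files; 10 spans roughly three orders of magnitude,
#: a realistic dynamic range for expression data.
_EXPR_LOG_SPAN = 10.0


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: planted factors and ownership."""

    G: np.ndarray  # genes x R*
    P: np.ndarray  # samples x R*
    O: np.ndarray  # omics x R*
    labels: dict[str, str]
    label_features: dict[str, list[int]]
    signal: float
    noise_sd: float
    seed: int
    tensor: OmicsTensor | None = None


def _omics_factor(
    routing: str | Sequence[int] | np.ndarray,
    n_omics: int,
    rank: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(routing, np.ndarray):
        if routing.shape != (n_omics, rank):
            raise ValueError(f"routing array must be ({n_omics}, {rank})")
        return routing.astype(float)
    if isinstance(routing, str):
        if routing == "uniform":
            return rng.uniform(0.5, 1.0, size=(n_omics, rank))
        if routing == "ge_me":
            # alternate components between the first two layers; the third
            # layer carries only a faint echo of every component
            O = np.full((n_omics, rank), 0.05)
            for f in range(rank):
                O[f % 2, f] = 1.0
            return O
        if routing == "round_robin":
            O = np.full((n_omics, rank), 0.05)
            for f in range(rank):
                O[f % n_omics, f] = 1.0
            return O
        raise ValueError(f"unknown omics routing {routing!r}")
    # explicit dominant-omics index per component
    O = np.full((n_omics, rank), 0.05)
    for f, k in enumerate(routing):
        O[int(k), f] = 1.0
    return O


def generate(
    n_genes: int = 300,
    n_samples: int = 80,
    n_omics: int = 3,
    rank_true: int = 8,
    n_labels: int = 4,
    signal: float = 1.0,
    noise_sd: float = 0.05,
    omics_routing: str | Sequence[int] | np.ndarray = "uniform",
    seed: int = 0,
    gene_support: float = 0.05,
    baseline: float = 0.05,
) -> tuple[OmicsTensor, LabelTable, SyntheticTruth]:
    """Generate a cohort with planted label-specific CP components.

    Component f is owned by label ``f % n_labels``; samples of the owner
    load ``signal`` plus half-normal jitter, other samples a small
    uniform baseline.  Gene factors put uniform(0.5, 1.5) weight on a
    random ``gene_support`` fraction of genes per component.  The noise
    is Gaussian with sd ``noise_sd``, truncated at zero, applied before
    per-slice min-max scaling.
    """
    if rank_true < n_labels:
        raise ValueError(
            f"rank_true={rank_true} < n_labels={n_labels}: cannot plant one "
            "component per label"
        )
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    label_names = [f"L{c + 1}" for c in range(n_labels)]
    label_of = {s: label_names[j % n_labels] for j, s in enumerate(sample_ids)}
    label_features = {
        lab: [f for f in range(rank_true) if f % n_labels == c]
        for c, lab in enumerate(label_names)
    }

    P = rng.uniform(0.0, baseline * signal, size=(n_samples, rank_true))
    for j, s in enumerate(sample_ids):
        for f in label_features[label_of[s]]:
            P[j, f] = signal + abs(rng.normal(0.0, 0.25 * signal))

    G = np.zeros((n_genes, rank_true))
    n_support = max(1, int(round(gene_support * n_genes)))
    for f in range(rank_true):
        support = rng.choice(n_genes, size=n_support, replace=False)
        G[support, f] = rng.uniform(0.5, 1.5, size=n_support)

    O = _omics_factor(omics_routing, n_omics, rank_true, rng)

    raw = np.einsum("ir,jr,kr->ijk", G, P, O)
    if noise_sd > 0:
        raw = np.maximum(raw + rng.normal(0.0, noise_sd, size=raw.shape), 0.0)

    omics_names = list(DEFAULT_OMICS[:n_omics]) + [
        f"O{k + 1}" for k in range(len(DEFAULT_OMICS), n_omics)
    ]
    slices = []
    for k in range(n_omics):
        m = OmicsMatrix(omics_names[k], gene_ids, sample_ids, raw[:, :, k])
        scaled, _ = minmax_scale_slice(m)
        slices.append(scaled.values)
    tensor = OmicsTensor(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        omics_names=omics_names,
        values=np.stack(slices, axis=2),
    )
    truth = SyntheticTruth(
        G=G, P=P, O=O, labels=label_of, label_features=label_features,
        signal=signal, noise_sd=noise_sd, seed=seed, tensor=tensor,
    )
    return tensor, LabelTable(labels=label_of), truth


def make_fixture_files(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write an on-disk file set that round-trips through the pipeline.

    Produces expression, methylation-probe and miRNA matrices plus the
    annotation, probe manifest, target map and label table.  Expression
    and miRNA values are obtained by inverting the log2 transform of the
    scaled slices (so the reading pipeline approximately reproduces the
    generated tensor); methylation probes carry the gene's beta value
    with small probe-level jitter, two probes per promoter.
    """
    if truth.tensor is None:
        raise ValueError("truth has no tensor attached")
    tensor = truth.tensor
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed + 1)
    gene_ids, sample_ids = tensor.gene_ids, tensor.sample_ids
    paths: dict[str, Path] = {}

    def _inverse_expr(slice_values: np.ndarray) -> np.ndarray:
        return np.power(2.0, _EXPR_LOG_SPAN * slice_values) - 1.0

    expr = OmicsMatrix("GE", gene_ids, sample_ids,
                       _inverse_expr(tensor.slice("GE").values))
    paths["expression"] = out_dir / "expression.tsv"
    write_matrix(expr, paths["expression"])

    # annotation: alternate strands, well-separated TSS on one chromosome
    ann_rows = []
    tss_of: dict[str, tuple[int, str]] = {}
    for i, g in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        tss = 50_000 + 10_000 * i
        tss_of[g] = (tss, strand)
        ann_rows.append(f"{g}\tchr1\t{strand}\t{tss}\tprotein_coding")
    paths["annotation"] = out_dir / "annotation.tsv"
    paths["annotation"].write_text(
        "gene_id\tchrom\tstrand\ttss\tbiotype\n" + "\n".join(ann_rows) + "\n"
    )

    # two probes per promoter, inside the strand-aware window
    me = tensor.slice("ME").values
    probe_ids: list[str] = []
    probe_rows: list[np.ndarray] = []
    manifest_rows: list[str] = []
    for i, g in enumerate(gene_ids):
        tss, strand = tss_of[g]
        offsets = (100, 200) if strand == "-" else (-100, -200)
        for p_idx, off in enumerate(offsets):
            pid = f"cg_{g}_{p_idx}"
            probe_ids.append(pid)
            jitter = rng.normal(0.0, 0.01, size=len(sample_ids))
            probe_rows.append(np.clip(me[i, :] + jitter, 0.0, 1.0))
            manifest_rows.append(f"{pid}\tchr1\t{tss + off}")
    probes = OmicsMatrix("methylation_probe", probe_ids, sample_ids,
                         np.vstack(probe_rows))
    paths["methylation_probes"] = out_dir / "methylation_probes.tsv"
    write_matrix(probes, paths["methylation_probes"])
    paths["probe_manifest"] = out_dir / "probe_manifest.tsv"
    paths["probe_manifest"].write_text(
        "probe_id\tchrom\tpos\n" + "\n".join(manifest_rows) + "\n"
    )

    # one dedicated miRNA per gene: the bundle mean is the identity
    mi = tensor.slice("MI").values
    mirna_ids = [f"mir_{g}" for g in gene_ids]
    mirna = OmicsMatrix("mirna", mirna_ids, sample_ids, _inverse_expr(mi))
    paths["mirna"] = out_dir / "mirna.tsv"
    write_matrix(mirna, paths["mirna"])
    paths["mirna_targets"] = out_dir / "mirna_targets.tsv"
    paths["mirna_targets"].write_text(
        "mirna_id\tgene_id\n"
        + "\n".join(f"{m}\t{g}" for m, g in zip(mirna_ids, gene_ids))
        + "\n"
    )

    paths["labels"] = out_dir / "labels.tsv"
    write_labels(LabelTable(labels=truth.labels), paths["labels"])

    truth_json = {
        "seed": truth.seed,
        "signal": truth.signal,
        "noise_sd": truth.noise_sd,
        "label_features": truth.label_features,
        "G": truth.G.tolist(),
        "P": truth.P.tolist(),
        "O": truth.O.tolist(),
    }
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(truth_json))
    return paths
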