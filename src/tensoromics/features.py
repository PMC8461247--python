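"""Phenotype-specific feature selection on the patient component.

For each class label a one-vs-rest lasso is fitted on the rows of the
patient factor C_p:

    min_w  sum_i (y_i - sum_f z_if w_f)^2  +  alpha * sum_f |w_f|

with y_i = 1 for samples of the label and 0 otherwise, and z the C_p
entries.  The objective is exactly as written — no 1/M factor and no
intercept unless requested — so the coordinate-descent soft threshold
sits at alpha/2.  Surviving (nonzero-weight) features are ranked by
|w_f| and the top 20% kept.  Genes then attach to features by the argmax
of their C_g row, and each feature attaches to the omics layer with the
largest C_o loading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from tensoromics.io import LabelTable

logger = logging.getLogger(__name__)

_ZERO = 1e-12


@dataclass
class FeatureSelection:
    """Per-label lasso weights and the surviving feature subset.

    ``selected`` and ``nonzero`` hold 0-based feature indices with
    selected ⊆ nonzero; |selected| = ceil(top_fraction * |nonzero|)
    whenever any weight survives.
    """

    label: str
    alpha: float
    weights: np.ndarray
    nonzero: list[int]
    selected: list[int]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.nonzero):
            raise ValueError("selected features must be a subset of nonzero features")


@dataclass
class GeneFeatureAssignment:
    """Argmax maps from genes and omics layers onto the rank features."""

    gene_feature: np.ndarray  # (N,) feature index per gene
    feature_omics: np.ndarray  # (R,) omics index per feature
    label_genes: dict[str, list[int]] = field(default_factory=dict)
    gene_ids: list[str] | None = None
    omics_names: list[str] | None = None


def soft_threshold_1d(z: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Closed-form lasso solution for a single-feature design.

    Minimizes sum_i (y_i - z_i w)^2 + alpha |w|; the soft threshold sits
    at alpha/2, so w = sign(z.y) * max(|z.y| - alpha/2, 0) / z.z.  Used
    as the independent oracle for the coordinate-descent solver.
    """
    zy = float(z @ y)
    zz = float(z @ z)
    if zz <= _ZERO:
        return 0.0
    return math.copysign(max(abs(zy) - alpha / 2.0, 0.0), zy) / zz


def lasso_cd(
    Z: np.ndarray,
    y: np.ndarray,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    intercept: bool = False,
) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent on the un-normalized lasso objective.

    Iterates w_f <- S(z_f . r_f, alpha/2) / (z_f . z_f) with r_f the
    partial residual excluding feature f, until the largest coordinate
    change falls below ``tol``.  With ``intercept`` the data are centered
    first and the unpenalized intercept recovered afterwards.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    z_mean = Z.mean(axis=0) if intercept else np.zeros(Z.shape[1])
    y_mean = y.mean() if intercept else 0.0
    Zc, yc = Z - z_mean, y - y_mean
    n, p = Zc.shape
    col_sq = np.einsum("ij,ij->j", Zc, Zc)
    w = np.zeros(p)
    resid = yc.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for f in range(p):
            if col_sq[f] <= _ZERO:
                continue
            rho = Zc[:, f] @ resid + w[f] * col_sq[f]
            new = math.copysign(max(abs(rho) - alpha / 2.0, 0.0), rho) / col_sq[f]
            delta = new - w[f]
            if delta != 0.0:
                resid -= delta * Zc[:, f]
                w[f] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    b0 = float(y_mean - z_mean @ w) if intercept else 0.0
    return w, b0


def _top_fraction(
    weights: np.ndarray, nonzero: list[int], fraction: float
) -> list[int]:
    """Top-|w| subset: ceil(fraction * n), at least 1, ties to lower index."""
    if not nonzero:
        return []
    n_keep = max(1, math.ceil(fraction * len(nonzero)))
    ranked = sorted(nonzero, key=lambda f: (-abs(weights[f]), f))
    return sorted(ranked[:n_keep])


def _label_vector(
    labels: LabelTable | Sequence[str], sample_ids: Sequence[str] | None, n: int
) -> np.ndarray:
    if isinstance(labels, LabelTable):
        if sample_ids is None:
            raise ValueError("sample_ids required when labels is a LabelTable")
        return labels.vector(sample_ids)
    arr = np.asarray(labels, dtype=object)
    if arr.shape[0] != n:
        raise ValueError("label vector length does not match C_p rows")
    return arr


def l1_select(
    C_p: np.ndarray,
    labels: LabelTable | Sequence[str],
    label: str,
    alpha: float = 0.01,
    sample_ids: Sequence[str] | None = None,
    top_fraction: float = 0.2,
    intercept: bool = False,
    tol: float = 1e-6,
) -> FeatureSelection:
    """One-vs-rest lasso for a single label on the patient component.

    All samples participate with target 1 for the label and 0 for the
    rest.  Nonzero-weight features are ranked by |w| (ties to the lower
    index) and the top ``top_fraction`` kept, at least one when any
    weight survives.
    """
    C_p = np.asarray(C_p, dtype=float)
    y_cls = _label_vector(labels, sample_ids, C_p.shape[0])
    n_pos = int(np.sum(y_cls == label))
    if n_pos < 2:
        raise ValueError(f"label {label!r} has {n_pos} sample(s); need >= 2")
    y = (y_cls == label).astype(float)
    w, b0 = lasso_cd(C_p, y, alpha, tol=tol, intercept=intercept)
    nonzero = [f for f in range(C_p.shape[1]) if abs(w[f]) > _ZERO]
    selected = _top_fraction(w, nonzero, top_fraction)
    return FeatureSelection(
        label=label, alpha=alpha, weights=w, nonzero=nonzero,
        selected=selected, intercept=b0,
    )


def select_all_labels(
    C_p: np.ndarray,
    labels: LabelTable | Sequence[str],
    alpha: float = 0.01,
    sample_ids: Sequence[str] | None = None,
    top_fraction: float = 0.2,
    intercept: bool = False,
) -> tuple[dict[str, FeatureSelection], list[int]]:
    """One lasso per label plus the union of all selected features.

    Features may serve several labels; the union is sorted.  Requires at
    least two distinct labels.
    """
    y_cls = _label_vector(labels, sample_ids, np.asarray(C_p).shape[0])
    classes = sorted(set(str(c) for c in y_cls))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    selections = {
        c: l1_select(
            C_p, y_cls, c, alpha=alpha, top_fraction=top_fraction, intercept=intercept
        )
        for c in classes
    }
    union = sorted(set().union(*(s.selected for s in selections.values())))
    return selections, union


def assign_genes(
    C_g: np.ndarray,
    selections: Mapping[str, FeatureSelection] | None = None,
    gene_ids: Sequence[str] | None = None,
    feature_omics: np.ndarray | None = None,
    omics_names: Sequence[str] | None = None,
) -> GeneFeatureAssignment:
    """Attach every gene to the feature where its C_g weight is maximal.

    Ties (including all-zero rows) resolve to the lowest feature index.
    Each label's gene set collects the genes whose feature lies in that
    label's selected set; gene sets may overlap across labels.
    """
    C_g = np.asarray(C_g, dtype=float)
    gene_feature = np.argmax(C_g, axis=1)
    n_flat = int(np.sum(np.ptp(C_g, axis=1) <= _ZERO))
    if n_flat:
        logger.warning("assign_genes: %d gene rows are constant; assigned feature 0", n_flat)
    label_genes: dict[str, list[int]] = {}
    if selections:
        for label, sel in selections.items():
            wanted = set(sel.selected)
            label_genes[label] = [
                int(i) for i in np.nonzero(np.isin(gene_feature, list(wanted)))[0]
            ]
    return GeneFeatureAssignment(
        gene_feature=gene_feature,
        feature_omics=feature_omics if feature_omics is not None else np.array([], int),
        label_genes=label_genes,
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        omics_names=list(omics_names) if omics_names is not None else None,
    )


def assign_omics(C_o: np.ndarray) -> np.ndarray:
    """Attach every feature to the omics layer with the largest loading.

    ``C_o`` is (n_omics x R); ties resolve to the first omics in tensor
    order, and perfectly flat columns are flagged as ambiguous.
    """
    C_o = np.asarray(C_o, dtype=float)
    n_flat = int(np.sum(np.ptp(C_o, axis=0) <= _ZERO))
    if n_flat:
        logger.warning("assign_omics: %d feature columns are flat (ambiguous)", n_flat)
    return np.argmax(C_o, axis=0)
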