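"""Non-negative PARAFAC/CP decomposition and rank estimation.

The tensor T (genes x samples x omics) is modelled as a sum of R
non-negative rank-1 terms,

    T ~ sum_f  g_f (x) p_f (x) o_f,

fitted by minimizing the Frobenius norm of the residual under
non-negativity, using HALS-style alternating updates (hierarchical
alternating least squares: each factor column is updated in closed form
while the rest are held fixed, which keeps the objective monotone).
Scale indeterminacy is resolved by normalizing the gene and omics factor
columns to unit L2 norm, pushing all magnitude into the patient factor,
which is the component downstream feature selection consumes.

Rank estimation follows the NMF consensus-clustering recipe: repeated
seeded NMF runs per candidate rank, a sample co-clustering consensus
matrix, the dispersion score rho = mean(4 (C_ij - 1/2)^2) in [0, 1], and
an elbow rule on the dispersion curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from tensoromics.genecentric import OmicsTensor

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class DecompResult:
    """Factor matrices and fit diagnostics of one CP decomposition.

    ``C_g`` (genes x R) and ``C_o`` (omics x R) have unit-L2 columns;
    ``C_p`` (samples x R) carries the component magnitudes.
    """

    C_g: np.ndarray
    C_p: np.ndarray
    C_o: np.ndarray
    rank: int
    relative_error: float
    seed: int
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        for name, f in (("C_g", self.C_g), ("C_p", self.C_p), ("C_o", self.C_o)):
            if np.min(f) < 0:
                raise ValueError(f"{name} contains negative entries")


@dataclass
class RankScan:
    """Dispersion curve over candidate ranks and the chosen elbow."""

    ranks: list[int]
    dispersion: list[float]
    chosen: int
    n_runs: int


def _as_array(tensor: OmicsTensor | np.ndarray) -> np.ndarray:
    values = tensor.values if isinstance(tensor, OmicsTensor) else np.asarray(tensor)
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"expected a third-order tensor, got ndim={values.ndim}")
    if not np.isfinite(values).all():
        raise ValueError("tensor contains non-finite entries")
    if values.min() < 0:
        raise ValueError("tensor must be non-negative")
    return values


def _unfoldings(T: np.ndarray) -> list[np.ndarray]:
    n, m, k = T.shape
    return [
        T.reshape(n, m * k),
        np.ascontiguousarray(T.transpose(1, 0, 2)).reshape(m, n * k),
        np.ascontiguousarray(T.transpose(2, 0, 1)).reshape(k, n * m),
    ]


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # column-wise Kronecker with the first argument's rows major
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _hals_sweep(
    factors: list[np.ndarray], unfolds: list[np.ndarray]
) -> tuple[list[np.ndarray], float]:
    """One sweep of HALS updates over all three modes.

    Returns the updated factors and the squared residual norm computed
    from the mode-2 quantities after its update (exact at sweep end).
    """
    err_sq = np.nan
    for mode in range(3):
        others = [factors[m] for m in range(3) if m != mode]
        kr = _khatri_rao(others[0], others[1])
        mttkrp = unfolds[mode] @ kr  # dim x R
        gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
        F = factors[mode]
        for r in range(F.shape[1]):
            denom = gram[r, r]
            if denom <= _EPS:
                F[:, r] = 0.0
                continue
            update = F[:, r] + (mttkrp[:, r] - F @ gram[:, r]) / denom
            F[:, r] = np.maximum(update, 0.0)
        if mode == 2:
            # ||T - That||^2 = ||T||^2 - 2<F, MTTKRP> + <G, F'F>
            cross = float(np.sum(F * mttkrp))
            quad = float(np.sum(gram * (F.T @ F)))
            err_sq = -2.0 * cross + quad
    return factors, err_sq


def parafac_nn(
    tensor: OmicsTensor | np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    n_starts: int = 5,
) -> DecompResult:
    """Fit a rank-R non-negative CP decomposition by multi-start HALS.

    Each start draws non-negative uniform factors from a seed derived
    from ``seed`` and the start index; the best start by relative
    reconstruction error is returned.  The objective is non-increasing
    across sweeps; iteration stops when the relative objective change
    falls below ``tol`` or after ``max_iter`` sweeps.

    The relative error is ||T - That||_F / ||T||_F, defined as 0 for an
    all-zero tensor.
    """
    T = _as_array(tensor)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    shape = T.shape
    norm_sq = float(np.sum(T * T))
    if norm_sq == 0.0:
        zero = [np.zeros((d, rank)) for d in shape]
        return DecompResult(*zero, rank=rank, relative_error=0.0, seed=seed,
                            n_iter=0, converged=True)
    unfolds = _unfoldings(T)
    norm = np.sqrt(norm_sq)

    best: tuple[float, list[np.ndarray], int, bool] | None = None
    for start in range(n_starts):
        rng = np.random.default_rng([seed, start])
        factors = [rng.uniform(0.1, 1.0, size=(d, rank)) for d in shape]
        # scale the start so its reconstruction has the tensor's norm;
        # otherwise the first sweep clips most columns to zero on sparse data
        init_norm_sq = float(
            np.sum(
                (factors[0].T @ factors[0])
                * (factors[1].T @ factors[1])
                * (factors[2].T @ factors[2])
            )
        )
        if init_norm_sq > _EPS:
            scale = (norm_sq / init_norm_sq) ** (1.0 / 6.0)
            factors = [f * scale for f in factors]
        prev = np.inf
        converged = False
        n_iter = 0
        for sweep in range(max_iter):
            factors, err_sq = _hals_sweep(factors, unfolds)
            obj = norm_sq + err_sq  # ||T||^2 - 2<.,.> + quad
            n_iter = sweep + 1
            if prev - obj > -1e-9 * max(abs(prev), 1.0) and np.isfinite(prev):
                rel_change = abs(prev - obj) / max(abs(prev), _EPS)
                if rel_change < tol:
                    converged = True
                    break
            prev = obj
        rel_err = float(np.sqrt(max(obj, 0.0)) / norm)
        if best is None or rel_err < best[0]:
            best = (rel_err, [f.copy() for f in factors], n_iter, converged)

    rel_err, factors, n_iter, converged = best
    C_g, C_p, C_o = _normalize_factors(*factors)
    return DecompResult(
        C_g=C_g, C_p=C_p, C_o=C_o, rank=rank, relative_error=rel_err,
        seed=seed, n_iter=n_iter, converged=converged,
    )


def _normalize_factors(
    C_g: np.ndarray, C_p: np.ndarray, C_o: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Push all column scale into the patient factor (C_g, C_o unit-L2)."""
    C_g, C_p, C_o = C_g.copy(), C_p.copy(), C_o.copy()
    for r in range(C_g.shape[1]):
        for F in (C_g, C_o):
            nrm = np.linalg.norm(F[:, r])
            if nrm > _EPS:
                F[:, r] /= nrm
                C_p[:, r] *= nrm
    return C_g, C_p, C_o


def reconstruct(result: DecompResult) -> np.ndarray:
    """Rebuild the tensor as the sum of R rank-1 outer products."""
    return np.einsum("ir,jr,kr->ijk", result.C_g, result.C_p, result.C_o)


def match_factors(
    planted: np.ndarray, recovered: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match recovered factor columns to planted ones by the Hungarian rule.

    Columns are compared by cosine similarity after unit normalization;
    the assignment maximizes total similarity.  Returns the permutation
    (planted column f corresponds to recovered column perm[f]) and the
    per-pair cosines.
    """

    def _unit(a: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(a, axis=0, keepdims=True)
        return a / np.where(nrm > _EPS, nrm, 1.0)

    cos = _unit(planted).T @ _unit(recovered)
    row, col = linear_sum_assignment(-cos)
    perm = np.empty(planted.shape[1], dtype=int)
    perm[row] = col
    return perm, cos[row, col]


def dispersion_from_consensus(consensus: np.ndarray) -> float:
    """Dispersion rho = mean(4 (C_ij - 1/2)^2) of a consensus matrix.

    1 means every pair of samples is always or never co-clustered
    (perfectly stable clustering); 0 means every pair co-clusters in
    exactly half the runs (maximal ambiguity).
    """
    consensus = np.asarray(consensus, dtype=float)
    return float(np.mean(4.0 * (consensus - 0.5) ** 2))


def consensus_dispersion(
    matrix: np.ndarray, rank: int, n_runs: int = 20, seed: int = 0
) -> float:
    """Consensus-clustering dispersion of repeated NMF at one rank.

    ``matrix`` is a gene x sample slice; each of ``n_runs`` seeded NMF
    runs assigns every sample to its maximum-coefficient basis, and the
    consensus matrix records the fraction of runs co-clustering each
    sample pair.
    """
    X = np.asarray(matrix, dtype=float)
    n_samples = X.shape[1]
    if rank >= n_samples:
        raise ValueError(f"rank {rank} must be < number of samples {n_samples}")
    consensus = np.zeros((n_samples, n_samples))
    rng = np.random.default_rng(seed)
    for run in range(n_runs):
        state = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=rank, init="random", solver="mu",
            beta_loss="frobenius", max_iter=300, tol=1e-5, random_state=state,
        )
        W = model.fit_transform(X)
        H = model.components_  # rank x samples
        assign = np.argmax(H, axis=0)
        consensus += (assign[:, None] == assign[None, :]).astype(float)
    consensus /= n_runs
    return dispersion_from_consensus(consensus)


def scan_ranks(
    matrix: np.ndarray,
    ranks: Sequence[int] = tuple(range(20, 201, 20)),
    n_runs: int = 20,
    seed: int = 0,
) -> RankScan:
    """Dispersion curve over candidate ranks plus the elbow choice."""
    ranks = sorted(set(int(r) for r in ranks))
    rho = [consensus_dispersion(matrix, r, n_runs=n_runs, seed=seed) for r in ranks]
    scan = RankScan(ranks=list(ranks), dispersion=rho, chosen=-1, n_runs=n_runs)
    scan.chosen = choose_rank(scan)
    return scan


def choose_rank(scan: RankScan) -> int:
    """Pick the elbow of the dispersion curve.

    The elbow is the interior candidate with the largest downward
    curvature, score_i = 2 rho_i - rho_{i-1} - rho_{i+1}: the last rank
    where dispersion is still high before its sharpest drop.  Ties break
    toward the smaller rank; a curve with no curvature (e.g., strictly
    linear) yields the smallest candidate with a warning.
    """
    ranks, rho = scan.ranks, scan.dispersion
    if not ranks:
        raise ValueError("empty rank scan")
    if len(ranks) == 1:
        return ranks[0]
    if len(ranks) == 2:
        logger.warning("choose_rank: two candidates, no interior elbow; using smaller")
        return ranks[0]
    scores = [
        2.0 * rho[i] - rho[i - 1] - rho[i + 1] for i in range(1, len(ranks) - 1)
    ]
    best = max(scores)
    if abs(best - min(scores)) < 1e-12:
        logger.warning("choose_rank: flat curvature, no elbow; using smallest rank")
        return ranks[0]
    idx = scores.index(best) + 1  # interior offset; index() takes first = smaller rank
    return ranks[idx]
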