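"""Consensus seed training and the final seeded factorisation.

For one trial rank ``K_tilde`` the scheme is:

1. ``R`` repetitions of ~80% column resampling of the filtered matrix.
2. Per repetition, ``n_inits`` randomly initialised multiplicative-update
   factorisations run for ``mult_steps`` iterations; the lowest-residual
   pair is refined to convergence by alternating least squares with
   non-negativity enforced by projection.
3. Per repetition and factor, genes are ranked by *exclusive weight*
   (own-factor weight minus the maximum weight in the other factors) and
   the top ``top_genes_consensus`` genes are recorded in a gene-by-gene
   co-occurrence consensus matrix.
4. Average-linkage hierarchical clustering of the consensus matrix into
   ``K_tilde`` gene clusters yields a seed matrix with loading
   ``seed_high`` for a gene's own cluster and ``seed_low`` elsewhere.
5. A final factorisation of the filtered matrix starts from that seed
   and runs to convergence, giving the robust ``(W', H')`` pair.

The multiplicative updates are the standard Frobenius-norm ones, which
never increase the objective; alternating least squares follows the
classical clip-to-zero scheme, with the best iterate retained so the
returned pair is never worse than its starting point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd

from .types import (
    ExpressionMatrix,
    FactorizationResult,
    FilteredMatrix,
    TrainingConfig,
    ValidationError,
)

__all__ = [
    "subsample_columns",
    "inner_nmf",
    "rank_features_by_exclusive_weight",
    "ConsensusMatrix",
    "update_consensus",
    "cluster_consensus_to_seed",
    "final_seeded_nmf",
    "train_seed",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# resampling

def subsample_columns(
    A_prime: FilteredMatrix, fraction: float, rng: np.random.Generator
) -> FilteredMatrix:
    """Sample ``ceil(fraction * M)`` distinct columns without replacement.

    Column order of the input is preserved; feature rows are unchanged.
    """
    M = A_prime.n_samples
    n = math.ceil(fraction * M)
    if n < 1 or n > M:
        raise ValidationError(f"cannot sample {n} of {M} columns")
    cols = np.sort(rng.choice(M, size=n, replace=False))
    return FilteredMatrix(
        A_prime.values[:, cols],
        list(A_prime.feature_ids),
        [A_prime.sample_ids[j] for j in cols],
        provenance=dict(getattr(A_prime, "provenance", {})),
    )


# ---------------------------------------------------------------------------
# solvers

def _objective(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(A - W @ H, "fro"))


def _mu_batch(A: np.ndarray, W: np.ndarray, H: np.ndarray, n_steps: int,
              record: list | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Batched Lee–Seung multiplicative updates (Frobenius norm).

    ``W`` has shape (batch, F, K) and ``H`` (batch, K, M); ``A`` is shared
    across the batch.  Residuals after each full step may be recorded.
    """
    Ab = A[None]
    for _ in range(n_steps):
        Wt = W.transpose(0, 2, 1)
        H *= (Wt @ Ab) / (Wt @ W @ H + _EPS)
        Ht = H.transpose(0, 2, 1)
        W *= (Ab @ Ht) / (W @ (H @ Ht) + _EPS)
        if record is not None:
            R = Ab - W @ H
            record.append(np.sqrt((R * R).sum(axis=(1, 2))))
    return W, H


def _clipped_ls(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Unconstrained least squares ``min ||M X - B||`` clipped at zero.

    Solves the normal equations; falls back to SVD least squares when
    the Gram matrix is singular (e.g. an all-zero factor column).
    """
    G = M.T @ M
    try:
        X = np.linalg.solve(G, M.T @ B)
    except np.linalg.LinAlgError:
        X = np.linalg.lstsq(M, B, rcond=None)[0]
    return np.maximum(X, 0.0)


def _als_refine(
    A: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    patience: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternating least squares with negative entries clipped to zero.

    Iterates until the relative change of the residual norm falls below
    ``tol``, the best objective has not improved (relatively, by
    ``tol``) for ``patience`` consecutive iterations — clipped ALS can
    cycle without converging — or ``max_iter`` is reached.  The best
    iterate seen (including the starting pair) is returned, so the
    objective never regresses.
    """
    best_obj = _objective(A, W, H)
    best = (W.copy(), H.copy())
    prev = best_obj
    stall = 0
    for _ in range(max_iter):
        H = _clipped_ls(W, A)
        W = _clipped_ls(H.T, A.T).T
        obj = _objective(A, W, H)
        if not np.isfinite(obj):
            break
        if obj < best_obj * (1.0 - tol):
            best_obj = obj
            best = (W.copy(), H.copy())
            stall = 0
        else:
            if obj < best_obj:
                best_obj = obj
                best = (W.copy(), H.copy())
            stall += 1
            if stall >= patience:
                break
        if prev > 0 and abs(prev - obj) / max(prev, _EPS) < tol:
            break
        prev = obj
    return best[0], best[1], best_obj


def _normalize_scale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the per-factor scale indeterminacy: H rows get unit 2-norm.

    The product W·H is unchanged; factor strength moves into the W
    columns.  This keeps the NNLS projections downstream on comparable
    scales (weak factors end up with small gene weights rather than
    arbitrarily inflated ones).
    """
    norms = np.linalg.norm(H, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    return W * norms[None, :], H / norms[:, None]


@dataclass
class InnerNMFDetails:
    """Diagnostics of one repetition (all candidates and their paths)."""

    candidate_objectives: np.ndarray = field(default_factory=lambda: np.empty(0))
    step_objectives: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    selected: int = -1
    refined_objective: float = np.nan


def inner_nmf(
    A_dd: FilteredMatrix | np.ndarray,
    K_tilde: int,
    cfg: TrainingConfig,
    rng: np.random.Generator,
    details: InnerNMFDetails | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One repetition: multi-start multiplicative updates + ALS refinement.

    Returns the refined non-negative ``(W, H)`` pair with the smallest
    Frobenius residual among ``cfg.n_inits`` random starts.
    """
    A = A_dd.values if isinstance(A_dd, ExpressionMatrix) else np.asarray(A_dd, float)
    F, m = A.shape
    if K_tilde >= min(F, m) + 1:
        raise ValidationError(f"K_tilde={K_tilde} too large for a {F}x{m} matrix")
    scale = math.sqrt(max(A.mean(), _EPS) / K_tilde)
    W = rng.random((cfg.n_inits, F, K_tilde)) * scale + _EPS
    H = rng.random((cfg.n_inits, K_tilde, m)) * scale + _EPS
    record: list | None = [] if details is not None else None
    W, H = _mu_batch(A, W, H, cfg.mult_steps, record)
    R = A[None] - W @ H
    objs = np.sqrt((R * R).sum(axis=(1, 2)))
    if np.all(~np.isfinite(objs)):
        raise ValidationError("all multiplicative-update candidates diverged")
    objs = np.where(np.isfinite(objs), objs, np.inf)
    pick = int(np.argmin(objs))
    Wr, Hr, obj = _als_refine(A, W[pick], H[pick], cfg.als_tol, cfg.als_max_iter)
    Wr, Hr = _normalize_scale(Wr, Hr)
    if details is not None:
        details.candidate_objectives = objs
        details.step_objectives = np.stack(record, axis=1) if record else np.empty((0, 0))
        details.selected = pick
        details.refined_objective = obj
    return Wr, Hr


# ---------------------------------------------------------------------------
# exclusive-weight ranking

def exclusive_weight_scores(W: np.ndarray, factor_index: int) -> np.ndarray:
    """Own-factor weight minus the max weight among the other factors.

    With a single column the weight itself is the score (degenerate
    case: there is no competing factor to subtract).
    """
    W = np.asarray(W, float)
    if W.ndim != 2:
        raise ValidationError("W must be 2-D")
    if W.shape[1] == 1:
        return W[:, 0].copy()
    others = np.delete(W, factor_index, axis=1)
    return W[:, factor_index] - others.max(axis=1)


def rank_features_by_exclusive_weight(W: np.ndarray, factor_index: int) -> np.ndarray:
    """Indices of all rows sorted by exclusive weight, descending.

    Ties are broken by input row order (stable sort).
    """
    scores = exclusive_weight_scores(W, factor_index)
    return np.argsort(-scores, kind="stable")


# ---------------------------------------------------------------------------
# consensus matrix

class ConsensusMatrix:
    """Gene-by-gene co-occurrence counts over top-gene selections.

    The matrix is indexed by the union of all genes ever admitted; the
    diagonal counts each gene's total admissions (a gene in the top set
    of two factors of one repetition is counted twice).
    """

    def __init__(self) -> None:
        self.genes: list = []
        self._index: dict = {}
        self.counts: np.ndarray = np.zeros((0, 0), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.genes)

    def _admit(self, genes) -> np.ndarray:
        new = [g for g in genes if g not in self._index]
        if new:
            n_old, n_new = len(self.genes), len(new)
            grown = np.zeros((n_old + n_new, n_old + n_new), dtype=np.int64)
            grown[:n_old, :n_old] = self.counts
            self.counts = grown
            for g in new:
                self._index[g] = len(self.genes)
                self.genes.append(g)
        return np.array([self._index[g] for g in genes], dtype=np.intp)

    def update(self, top_sets: list) -> None:
        """Record the top-gene sets of one repetition's factors."""
        for genes in top_sets:
            if len(set(genes)) != len(genes):
                raise ValidationError("top-gene set contains duplicates")
            idx = self._admit(genes)
            self.counts[np.ix_(idx, idx)] += 1

    def dissimilarity(self) -> np.ndarray:
        """1 - count_ij / max(count_ii, count_jj); zero on the diagonal."""
        d = np.diag(self.counts).astype(float)
        denom = np.maximum(d[:, None], d[None, :])
        denom[denom == 0] = 1.0
        dis = 1.0 - self.counts / denom
        np.fill_diagonal(dis, 0.0)
        return np.maximum(dis, 0.0)


def update_consensus(C: ConsensusMatrix, top_sets: list) -> ConsensusMatrix:
    """Functional wrapper over :meth:`ConsensusMatrix.update`."""
    C.update(top_sets)
    return C


def cluster_consensus_to_seed(
    C: ConsensusMatrix, K_tilde: int, cfg: TrainingConfig
) -> tuple[np.ndarray, list]:
    """Cluster the consensus genes into ``K_tilde`` groups and build the seed.

    Average-linkage hierarchical clustering on the count-ratio
    dissimilarity, cut at ``K_tilde`` clusters.  The returned seed matrix
    (consensus genes × ``K_tilde``) holds ``seed_high`` in a gene's own
    cluster column and ``seed_low`` elsewhere.
    """
    n = len(C)
    if n < K_tilde:
        raise ValidationError(f"consensus has {n} genes, fewer than K_tilde={K_tilde}")
    if K_tilde == 1:
        labels = np.zeros(n, dtype=int)
    else:
        dis = C.dissimilarity()
        Z = sch.linkage(ssd.squareform(dis, checks=False), method="average")
        labels = sch.fcluster(Z, t=K_tilde, criterion="maxclust") - 1
        labels = _force_k_clusters(labels, K_tilde)
    seed = np.full((n, K_tilde), cfg.seed_low, dtype=float)
    seed[np.arange(n), labels] = cfg.seed_high
    return seed, list(C.genes)


def _force_k_clusters(labels: np.ndarray, K: int) -> np.ndarray:
    """Guarantee exactly K non-empty clusters (splits the largest if short)."""
    labels = np.asarray(labels).copy()
    used = np.unique(labels)
    remap = {u: i for i, u in enumerate(used)}
    labels = np.array([remap[u] for u in labels])
    n_used = len(used)
    while n_used < K:
        sizes = np.bincount(labels, minlength=n_used)
        big = int(np.argmax(sizes))
        member = np.flatnonzero(labels == big)[-1]
        labels[member] = n_used
        n_used += 1
    return labels


# ---------------------------------------------------------------------------
# final seeded factorisation

def final_seeded_nmf(
    A_prime: FilteredMatrix,
    W_seed: np.ndarray,
    seed_genes: list,
    cfg: TrainingConfig,
) -> FactorizationResult:
    """Run the final factorisation of A' from the consensus-derived seed.

    The seed is expanded to the full filtered feature space (features
    absent from the consensus start at ``seed_low`` in every column),
    the initial ``H`` is the exact NNLS projection of each sample onto
    the seed, and alternating least squares then runs to convergence.
    """
    index = {g: i for i, g in enumerate(A_prime.feature_ids)}
    missing = [g for g in seed_genes if g not in index]
    if missing:
        raise ValidationError(
            f"{len(missing)} consensus genes absent from the filtered matrix "
            f"(first: {missing[0]!r})"
        )
    F = A_prime.n_features
    K = W_seed.shape[1]
    W0 = np.full((F, K), cfg.seed_low, dtype=float)
    rows = np.array([index[g] for g in seed_genes], dtype=np.intp)
    W0[rows] = W_seed
    A = A_prime.values
    H0 = np.empty((K, A.shape[1]))
    for j in range(A.shape[1]):
        H0[:, j] = scipy.optimize.nnls(W0, A[:, j])[0]
    W, H, obj = _als_refine(A, W0, H0, cfg.als_tol, cfg.als_max_iter)
    W, H = _normalize_scale(W, H)
    if not np.all(np.isfinite(W)) or not np.all(np.isfinite(H)):
        raise ValidationError("final factorisation diverged")
    if np.any(W.sum(axis=0) == 0):
        warnings.warn("final factorisation produced an all-zero factor column",
                      stacklevel=2)
    return FactorizationResult(W_prime=W, H_prime=H, objective=obj)


# ---------------------------------------------------------------------------
# full seed-training pipeline for one trial rank

def train_seed(
    A_prime: FilteredMatrix,
    cfg: TrainingConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> FactorizationResult:
    """Full seed training at ``cfg.K_tilde``: R resampled repetitions,
    consensus clustering, and the final seeded factorisation."""
    K = cfg.K_tilde
    if math.ceil(cfg.resample_fraction * A_prime.n_samples) < K:
        raise ValidationError("resampled sample count below K_tilde")
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.rng_seed)
    C = ConsensusMatrix()
    top_n = cfg.top_genes_consensus
    for child in seed_seq.spawn(cfg.R):
        rng = np.random.default_rng(child)
        A_dd = subsample_columns(A_prime, cfg.resample_fraction, rng)
        W, _ = inner_nmf(A_dd, K, cfg, rng)
        tops = []
        for i in range(K):
            order = rank_features_by_exclusive_weight(W, i)[:top_n]
            tops.append([A_prime.feature_ids[r] for r in order])
        C.update(tops)
    seed, genes = cluster_consensus_to_seed(C, K, cfg)
    result = final_seeded_nmf(A_prime, seed, genes, cfg)
    return result
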