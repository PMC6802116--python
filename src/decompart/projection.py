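"""Non-negative least-squares projections of a factorisation onto data.

After the final seeded factorisation, the compartment weights are
re-estimated per sample by NNLS against the filtered matrix (the H'
from the factorisation is discarded), and the gene weights are then
re-estimated per gene by NNLS against the *full* input matrix so every
gene — filtered out or not — obtains a weight in every factor.  The
full-matrix gene weights are what make genome-wide marker ranking and
later single-sample projection possible.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.optimize

from .types import ExpressionMatrix, FilteredMatrix, ValidationError

__all__ = ["nnls_solve", "project_compartment_weights", "project_gene_weights"]


def nnls_solve(M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve ``min ||Mx - b||_2 subject to x >= 0`` (global optimum)."""
    M = np.asarray(M, dtype=float)
    b = np.asarray(b, dtype=float)
    if M.ndim != 2 or M.shape[1] < 1:
        raise ValidationError("M must be 2-D with at least one column")
    if b.shape != (M.shape[0],):
        raise ValidationError(
            f"dimension mismatch: M is {M.shape}, b has length {b.shape}"
        )
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(b))):
        raise ValidationError("NNLS input contains NaN or infinity")
    x, _ = scipy.optimize.nnls(M, b)
    return x


def project_compartment_weights(
    W_prime: np.ndarray, A_prime: FilteredMatrix
) -> np.ndarray:
    """Definitive compartment weights: one NNLS per sample of A'.

    Solves ``min ||W' h_i - a'_i||`` with ``h_i >= 0`` for every sample
    column, replacing the H' produced by the factorisation itself.
    """
    W_prime = np.asarray(W_prime, dtype=float)
    if W_prime.shape[0] != A_prime.n_features:
        raise ValidationError(
            f"W' has {W_prime.shape[0]} rows but A' has {A_prime.n_features} features"
        )
    if np.any(W_prime.sum(axis=0) == 0):
        warnings.warn("W' contains an all-zero factor column; it is retained "
                      "with zero weight everywhere", stacklevel=2)
    K, M = W_prime.shape[1], A_prime.n_samples
    H = np.empty((K, M))
    A = A_prime.values
    for j in range(M):
        H[:, j] = scipy.optimize.nnls(W_prime, A[:, j])[0]
    return H


def project_gene_weights(H_tilde: np.ndarray, A: ExpressionMatrix) -> np.ndarray:
    """Genome-wide gene weights: one NNLS per feature row of the full A.

    Solves ``min ||H~^T w_j - a_j||`` with ``w_j >= 0`` for every row of
    the full input matrix (all N features, not only the filtered ones).
    """
    H_tilde = np.asarray(H_tilde, dtype=float)
    if H_tilde.shape[1] != A.n_samples:
        raise ValidationError(
            f"H~ has {H_tilde.shape[1]} samples but A has {A.n_samples}"
        )
    Ht = H_tilde.T  # M x K design matrix shared by all genes
    N = A.n_features
    W = np.empty((N, H_tilde.shape[0]))
    vals = A.values
    for j in range(N):
        W[j] = scipy.optimize.nnls(Ht, vals[j])[0]
    return W
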