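"""Feature filters producing the reduced training matrix A'.

Expression profiles keep the highly expressed genes (per-gene mean above
the third quartile of all per-gene means) and, among those, the
``n_keep`` most variable by standard deviation.  ATAC-seq counts keep
loci whose mean exceeds the grand mean of per-locus means *and* whose SD
exceeds the mean of per-locus SDs, then reduce to ``n_keep`` by the sum
of the mean rank and the SD rank.

Filters recognise their own output: re-applying a filter with identical
parameters to an already-filtered matrix is a no-op.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .types import ExpressionMatrix, FilteredMatrix, ValidationError

__all__ = ["filter_expression_features", "filter_atac_loci"]


def _provenance_matches(A: ExpressionMatrix, prov: dict) -> bool:
    return isinstance(A, FilteredMatrix) and A.provenance == prov


def _build(A: ExpressionMatrix, keep: np.ndarray, prov: dict) -> FilteredMatrix:
    keep = np.sort(keep)  # preserve original row order
    return FilteredMatrix(
        A.values[keep],
        [A.feature_ids[i] for i in keep],
        list(A.sample_ids),
        provenance=prov,
    )


def filter_expression_features(
    A: ExpressionMatrix,
    n_keep: int = 5000,
    log_transform: bool = False,
) -> FilteredMatrix:
    """Reduce an expression matrix to its highly expressed, variable genes.

    Step 1 keeps genes whose mean across samples is strictly above the
    third quartile (linear-interpolation quantile) of all per-gene
    means; step 2 keeps the ``n_keep`` survivors with the largest sample
    standard deviation.  If fewer than ``n_keep`` genes survive step 1,
    all survivors are returned with a warning.

    Set ``log_transform`` to rank variability on ``log1p`` values while
    returning the untransformed sub-matrix.
    """
    if n_keep < 1:
        raise ValidationError("n_keep must be positive")
    prov = {"filter": "expression", "n_keep": n_keep, "log_transform": log_transform}
    if _provenance_matches(A, prov):
        return A
    vals = np.log1p(A.values) if log_transform else A.values
    means = vals.mean(axis=1)
    q3 = np.quantile(means, 0.75)
    survivors = np.flatnonzero(means > q3)
    if survivors.size == 0:
        raise ValidationError("no features above the third quartile of means")
    sds = vals[survivors].std(axis=1, ddof=1)
    if np.all(sds == 0):
        raise ValidationError("no variable features among survivors")
    if survivors.size <= n_keep:
        if survivors.size < n_keep:
            warnings.warn(
                f"only {survivors.size} features survive the expression filter "
                f"(requested {n_keep}); keeping all survivors",
                stacklevel=2,
            )
        return _build(A, survivors, prov)
    # stable sort => ties broken by input row order
    order = np.argsort(-sds, kind="stable")[:n_keep]
    return _build(A, survivors[order], prov)


def filter_atac_loci(A: ExpressionMatrix, n_keep: int = 8000) -> FilteredMatrix:
    """Reduce an ATAC count matrix to its most open, variable loci.

    Keeps loci with per-locus mean above the grand mean of all per-locus
    means and per-locus SD above the mean of all per-locus SDs; if more
    than ``n_keep`` survive, the survivors with the largest
    (mean rank + SD rank) are kept so neither criterion dominates.
    """
    if n_keep < 1:
        raise ValidationError("n_keep must be positive")
    prov = {"filter": "atac", "n_keep": n_keep}
    if _provenance_matches(A, prov):
        return A
    means = A.values.mean(axis=1)
    sds = A.values.std(axis=1, ddof=1)
    survivors = np.flatnonzero((means > means.mean()) & (sds > sds.mean()))
    if survivors.size == 0:
        raise ValidationError("no loci pass the mean/SD filter")
    if survivors.size <= n_keep:
        return _build(A, survivors, prov)
    rank_sum = rankdata(means[survivors]) + rankdata(sds[survivors])
    order = np.argsort(-rank_sum, kind="stable")[:n_keep]
    return _build(A, survivors[order], prov)
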