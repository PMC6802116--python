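"""Single-sample compartment weight estimation from saved gene weights.

Given pre-computed gene weights W from a de novo deconvolution and a
new bulk measurement B (even a single sample), compartment weights are
the NNLS solution of ``min ||W h_i - b_i||`` per sample, restricted to
the features shared between B and W.  Weights over a declared
compartment subset are normalised to sum to one, and the basal/classical
tumour-weight ratio calls the sample Basal-like (ratio >= 1) or
Classical (ratio < 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .projection import nnls_solve
from .types import (
    CompartmentSet,
    ExpressionMatrix,
    TrainingConfig,
    ValidationError,
    WeightEstimate,
)

__all__ = [
    "estimate_weights",
    "normalize_weights",
    "basal_classical_metrics",
    "tenfold_cv",
]


def _reference(W_ref) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(W_ref, CompartmentSet):
        return W_ref.W_final, W_ref.feature_ids, W_ref.names
    W, feature_ids, names = W_ref
    return np.asarray(W, float), list(feature_ids), list(names)


def estimate_weights(
    B: ExpressionMatrix,
    W_ref: CompartmentSet | tuple,
    normalize_subset: list[int] | None = None,
) -> list[WeightEstimate]:
    """Project new samples onto saved gene weights by per-sample NNLS.

    ``B`` and the reference are restricted to their shared features
    (reference rows without a match are dropped, not imputed).  Fails if
    nothing is shared; warns when less than half of the reference
    features are matched, or when the value scales differ by more than
    tenfold (the projection assumes B is on the training scale).
    """
    W, ref_features, names = _reference(W_ref)
    b_index = {g: i for i, g in enumerate(B.feature_ids)}
    shared_ref_rows = [i for i, g in enumerate(ref_features) if g in b_index]
    if not shared_ref_rows:
        raise ValidationError("no shared features between B and the reference W")
    if len(shared_ref_rows) < 0.5 * len(ref_features):
        warnings.warn(
            f"only {len(shared_ref_rows)} of {len(ref_features)} reference "
            "features matched in B", stacklevel=2,
        )
    b_rows = [b_index[ref_features[i]] for i in shared_ref_rows]
    Wm = W[shared_ref_rows]
    Bm = B.values[b_rows]
    ref_scale = np.mean(np.abs(Wm.sum(axis=1))) or 1.0
    b_scale = np.mean(Bm) or 1.0
    # W columns are on the scale of the training data's gene space
    if max(b_scale / ref_scale, ref_scale / b_scale) > 10:
        warnings.warn(
            "value range of B differs from the reference gene weights by "
            "more than tenfold; check that B is on the training scale",
            stacklevel=2,
        )
    out = []
    for j, sid in enumerate(B.sample_ids):
        raw = nnls_solve(Wm, Bm[:, j])
        est = WeightEstimate(
            sample_id=sid, raw_weights=raw, n_genes_used=len(shared_ref_rows)
        )
        if normalize_subset is not None:
            est.normalized_weights, est.all_zero = normalize_weights(
                raw, normalize_subset
            )
        out.append(est)
    return out


def normalize_weights(
    raw: np.ndarray, subset: list[int] | np.ndarray
) -> tuple[np.ndarray, bool]:
    """Normalise the weights of a compartment subset to sum to one.

    Returns the normalised subset vector (in subset order) and a flag
    that is True when every subset weight is zero (the vector is then
    left at zero rather than divided).
    """
    subset = np.asarray(subset, dtype=np.intp)
    if subset.size == 0:
        raise ValidationError("empty compartment subset")
    sub = np.asarray(raw, dtype=float)[subset]
    total = sub.sum()
    if total == 0:
        return np.zeros(subset.size), True
    return sub / total, False


def basal_classical_metrics(
    weights: WeightEstimate | np.ndarray,
    basal_index: int,
    classical_index: int,
) -> tuple[float, float, str]:
    """Basal/classical ratio, difference, and the binary subtype call.

    ``ratio >= 1`` calls Basal-like (boundary inclusive), ``< 1``
    Classical.  A zero classical weight with positive basal weight gives
    an infinite ratio and a Basal-like call.
    """
    if isinstance(weights, WeightEstimate):
        vec = (
            weights.normalized_weights
            if weights.normalized_weights is not None
            else weights.raw_weights
        )
    else:
        vec = np.asarray(weights, dtype=float)
    try:
        b, c = float(vec[basal_index]), float(vec[classical_index])
    except IndexError as exc:
        raise ValidationError("basal or classical compartment missing") from exc
    if c == 0:
        ratio = np.inf if b > 0 else np.nan
        warnings.warn("classical weight is zero; ratio is degenerate", stacklevel=2)
    else:
        ratio = b / c
    subtype = "Basal-like" if ratio >= 1 else "Classical"
    return ratio, b - c, subtype


def tenfold_cv(
    A: ExpressionMatrix,
    run_denovo,
    rng_seed: int = 0,
    n_folds: int = 10,
) -> "pd.DataFrame":
    """Cross-validated reproducibility of compartment weights.

    Samples are partitioned into ``n_folds`` folds.  For each fold, a
    full de novo deconvolution runs on the remaining folds, the held-out
    samples are projected onto the resulting gene weights, and the fold
    compartments are matched to the full-data compartments by top-250
    overlap (Hungarian assignment).  Reported per full-data compartment:
    the Pearson correlation between cross-validated and full-data
    weights over all samples.

    ``run_denovo`` is a callable mapping an :class:`ExpressionMatrix`
    to a ``(CompartmentSet, FactorTree)`` pair.
    """
    import pandas as pd

    M = A.n_samples
    if M < n_folds:
        raise ValidationError(f"need at least {n_folds} samples, got {M}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(M)
    folds = [np.sort(perm[i::n_folds]) for i in range(n_folds)]

    full_set, _ = run_denovo(A)
    full_tops = _top_sets(full_set)
    cv_weights = np.full((full_set.n_compartments, M), np.nan)

    for fold in folds:
        train_cols = np.setdiff1d(np.arange(M), fold)
        A_train = ExpressionMatrix(
            A.values[:, train_cols],
            list(A.feature_ids),
            [A.sample_ids[j] for j in train_cols],
        )
        fold_set, _ = run_denovo(A_train)
        B = ExpressionMatrix(
            A.values[:, fold],
            list(A.feature_ids),
            [A.sample_ids[j] for j in fold],
        )
        ests = estimate_weights(B, fold_set)
        H_fold = np.column_stack([e.raw_weights for e in ests])
        for full_k, fold_k in _match_by_overlap(full_tops, _top_sets(fold_set)):
            cv_weights[full_k, fold] = H_fold[fold_k]

    rows = []
    for k, comp in enumerate(full_set.compartments):
        mask = ~np.isnan(cv_weights[k])
        if mask.sum() >= 3 and np.std(cv_weights[k, mask]) > 0:
            r = scipy.stats.pearsonr(
                cv_weights[k, mask], full_set.H_final[k, mask]
            ).statistic
        else:
            r = np.nan
        rows.append((comp.name, comp.label, int(mask.sum()), r))
    return pd.DataFrame(
        rows, columns=["compartment", "label", "n_samples_matched", "pearson_r"]
    ).set_index("compartment")


def _top_sets(compset: CompartmentSet, n: int = 250) -> list[set]:
    from .seed_training import rank_features_by_exclusive_weight

    out = []
    for k in range(compset.n_compartments):
        order = rank_features_by_exclusive_weight(compset.W_final, k)[:n]
        out.append({compset.feature_ids[i] for i in order})
    return out


def _match_by_overlap(
    tops_a: list[set], tops_b: list[set], min_overlap: int = 100
) -> list[tuple[int, int]]:
    """Hungarian matching of compartments by top-gene overlap.

    Pairs sharing no more than ``min_overlap`` top genes are treated as
    unmatched (the same >100-gene threshold that defines 'the same
    compartment' in minor labelling); a compartment absent from one run
    then simply stays unmatched instead of pairing on background genes.
    """
    if not tops_a or not tops_b:
        return []
    overlap = np.array([[len(a & b) for b in tops_b] for a in tops_a], dtype=float)
    ra, rb = scipy.optimize.linear_sum_assignment(-overlap)
    return [(int(i), int(j)) for i, j in zip(ra, rb) if overlap[i, j] > min_overlap]
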