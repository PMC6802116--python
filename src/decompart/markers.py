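"""Marker-gene selection and ranked-list gene-set enrichment.

Markers of a compartment are the genes whose positive exclusive weight
(own-compartment weight minus the best competing weight) stands
exponentially above the rest of the ranking — operationally, the genes
above the knee of the normalised ranking curve, where the knee is the
point of maximum perpendicular distance to the chord joining the
curve's endpoints.  Enrichment of a named gene set in a compartment's
full ranking is assessed by the two-sample Kolmogorov–Smirnov statistic
between the rank positions of members and non-members, with
Benjamini–Hochberg correction across sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .seed_training import exclusive_weight_scores, rank_features_by_exclusive_weight
from .types import CompartmentSet, MarkerList, ValidationError

__all__ = ["select_markers", "knee_index", "ks_enrichment"]


def knee_index(y: np.ndarray) -> int:
    """Knee of a decreasing curve by maximum chord distance.

    Both axes are normalised to [0, 1] so the knee is scale-free; the
    first index attaining the maximum distance is returned.  For a
    (near-)linear curve every distance is ~0 and the knee is index 0.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        return max(n - 1, 0)
    x = np.linspace(0.0, 1.0, n)
    span = y[0] - y[-1]
    yn = (y - y[-1]) / span if span != 0 else np.zeros(n)
    # distance from (x, yn) to the chord joining (0, yn[0]) and (1, yn[-1])
    dist = np.abs((yn[-1] - yn[0]) * x - yn + yn[0]) / np.hypot(yn[-1] - yn[0], 1.0)
    return int(np.argmax(dist))


def select_markers(
    compset_or_W: CompartmentSet | np.ndarray,
    compartment_index: int,
    feature_ids: list[str] | None = None,
) -> MarkerList:
    """Markers of one compartment: genes above the geometric knee.

    Exclusive-weight scores are computed against the other compartments,
    negatives discarded, the positives normalised to [0, 1] by their
    maximum, and the genes strictly above the knee of the resulting
    ranking curve returned (at least one gene when any score is
    positive).
    """
    if isinstance(compset_or_W, CompartmentSet):
        W = compset_or_W.W_final
        feature_ids = compset_or_W.feature_ids
        comp_id = compset_or_W.compartments[compartment_index].factor_id
    else:
        W = np.asarray(compset_or_W, dtype=float)
        if feature_ids is None:
            feature_ids = [str(i) for i in range(W.shape[0])]
        comp_id = str(compartment_index)
    order = rank_features_by_exclusive_weight(W, compartment_index)
    scores = exclusive_weight_scores(W, compartment_index)[order]
    positive = scores > 0
    if not positive.any():
        warnings.warn(
            f"compartment {comp_id}: no gene with positive exclusive weight",
            stacklevel=2,
        )
        return MarkerList(comp_id, [], np.empty(0))
    order, scores = order[positive], scores[positive]
    norm = scores / scores.max()
    n_markers = max(knee_index(norm), 1)
    idx = order[:n_markers]
    return MarkerList(
        compartment_id=comp_id,
        markers=[feature_ids[i] for i in idx],
        scores=norm[:n_markers],
    )


def ks_enrichment(
    ranking: list[str],
    gene_sets: dict[str, list[str]],
    method: str = "asymp",
) -> pd.DataFrame:
    """Ranked-list enrichment of gene sets by the two-sample KS statistic.

    For each set, member rank positions are compared with non-member
    positions; ``method`` is passed to :func:`scipy.stats.ks_2samp`
    (``"asymp"`` default, ``"exact"`` for small sets).  Benjamini–
    Hochberg q-values are computed across all tested sets.  Sets with no
    member in the ranking are skipped with a warning.
    """
    pos = {g: i for i, g in enumerate(ranking)}
    rows = []
    for name, members in gene_sets.items():
        in_pos = np.array(sorted(pos[g] for g in members if g in pos), dtype=float)
        if in_pos.size == 0:
            warnings.warn(f"gene set {name!r} has no member in the ranking",
                          stacklevel=2)
            continue
        member_set = {g for g in members if g in pos}
        out_pos = np.array(
            [i for g, i in pos.items() if g not in member_set], dtype=float
        )
        if out_pos.size == 0:
            warnings.warn(f"gene set {name!r} covers the whole ranking", stacklevel=2)
            continue
        res = scipy.stats.ks_2samp(in_pos, out_pos, method=method)
        rows.append((name, in_pos.size, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["set", "n_in_ranking", "D", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = np.empty(0)
    return df.set_index("set")
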