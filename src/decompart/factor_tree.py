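"""Factor scoring, cross-rank linkage, and the trial-rank schedule.

Each factor of a run at rank ``K`` is compared with every factor of the
run at ``K - 1`` by the overlap fraction of their top-250 exclusive-
weight genes.  The best-matching previous factor becomes the parent if
the overlap exceeds 0.1, and that overlap is the factor's *score*;
otherwise the factor is newly emerged (it still carries its maximum
overlap as score so that runs dominated by unstable factors register in
the schedule's medians).

The schedule starts at ``K = 2``, considers a run once its median
factor score rises above 0.5, and stops after four consecutive runs
with median below 0.5 (or at a hard cap).  Because the very first run
has no predecessor, a rank-1 pseudo-run is factorised solely to give
the ``K = 2`` factors something to be scored against.
"""

from __future__ import annotations

import json
import warnings
from typing import Callable

import numpy as np

from .seed_training import rank_features_by_exclusive_weight
from .types import Factor, FactorTree, RunResult, ScheduleResult, ValidationError

__all__ = [
    "top_n_features",
    "similarity",
    "link_runs",
    "schedule_K",
    "add_run",
    "tree_to_json",
    "tree_to_dot",
]

LINK_THRESHOLD = 0.1
TOP_N = 250


def top_n_features(
    W_tilde: np.ndarray, factor_index: int, feature_ids: list[str], n: int = TOP_N
) -> list[str]:
    """Top ``n`` features of a factor by exclusive weight."""
    if n > W_tilde.shape[0]:
        n = W_tilde.shape[0]
    order = rank_features_by_exclusive_weight(W_tilde, factor_index)[:n]
    return [feature_ids[i] for i in order]


def similarity(f_a: Factor, f_b: Factor) -> float:
    """Fraction of shared top genes between two factors (in [0, 1])."""
    a, b = f_a.top250, f_b.top250
    if not a or not b:
        raise ValidationError("both factors need populated top-gene lists")
    denom = max(len(a), len(b))
    return len(set(a) & set(b)) / denom


def add_run(tree: FactorTree, run: RunResult) -> None:
    """Register a run and create its (unscored) factors."""
    if run.K_tilde in tree.runs:
        raise ValidationError(f"run at K_tilde={run.K_tilde} already present")
    tree.runs[run.K_tilde] = run
    for i, fid in enumerate(run.factor_ids):
        tree.add_factor(
            Factor(
                factor_id=fid,
                K_tilde=run.K_tilde,
                column=i,
                top250=top_n_features(run.W_tilde, i, run.feature_ids),
            )
        )


def link_runs(tree: FactorTree, K_tilde: int) -> FactorTree:
    """Score and link every factor at ``K_tilde`` against rank ``K_tilde - 1``.

    The parent is the previous-rank factor with the largest overlap,
    provided the overlap exceeds 0.1 (ties go to the lower-index
    parent); below that the factor is newly emerged and unlinked, but
    its maximum overlap is still recorded as its score.
    """
    if K_tilde not in tree.runs or (K_tilde - 1) not in tree.runs:
        raise ValidationError(
            f"runs at K_tilde={K_tilde} and {K_tilde - 1} must both be present"
        )
    parents = tree.factors_at(K_tilde - 1)
    for child in tree.factors_at(K_tilde):
        sims = np.array([similarity(child, p) for p in parents])
        best = int(np.argmax(sims))  # first max wins: lower parent index
        child.score = float(sims[best])
        child.parent_id = parents[best].factor_id if sims[best] > LINK_THRESHOLD else None
    return tree


def median_score(tree: FactorTree, K_tilde: int) -> float:
    scores = [f.score for f in tree.factors_at(K_tilde) if f.score is not None]
    if not scores:
        raise ValidationError(f"no scores at K_tilde={K_tilde}")
    return float(np.median(scores))


def schedule_K(
    median_for_K: Callable[[int], float],
    K_min: int = 2,
    K_max: int = 30,
) -> ScheduleResult:
    """Drive the trial-rank schedule from a per-rank median-score callback.

    Runs ``K = K_min, K_min + 1, ...``; consideration begins at the
    first rank whose median factor score exceeds 0.5 and extends to the
    last executed rank; iteration stops after four consecutive ranks
    with median below 0.5, or at ``K_max`` with a warning.
    """
    medians: dict[int, float] = {}
    start = None
    consecutive_low = 0
    capped = False
    K = K_min - 1
    for K in range(K_min, K_max + 1):
        med = medians[K] = float(median_for_K(K))
        if med > 0.5:
            if start is None:
                start = K
            consecutive_low = 0
        elif med < 0.5:
            consecutive_low += 1
            if consecutive_low >= 4:
                break
        else:  # median exactly 0.5: neither starts consideration nor counts low
            consecutive_low = 0
    else:
        capped = True
        warnings.warn(
            f"trial-rank schedule reached the hard cap K_max={K_max} "
            "without satisfying the stop rule", stacklevel=2,
        )
    if start is None:
        raise ValidationError(
            "no run was ever considered (median factor score never exceeded "
            f"0.5; medians={medians})"
        )
    return ScheduleResult(
        considered_start=start,
        considered_end=K,
        last_K=K,
        capped=capped,
        medians=medians,
    )


# ---------------------------------------------------------------------------
# serialisation

def tree_to_json(tree: FactorTree) -> str:
    payload = {
        "considered_range": tree.considered_range,
        "factors": [
            {
                "factor_id": f.factor_id,
                "K_tilde": f.K_tilde,
                "column": f.column,
                "score": f.score,
                "parent_id": f.parent_id,
                "top250": f.top250,
            }
            for f in sorted(tree.factors.values(), key=lambda f: (f.K_tilde, f.column))
        ],
    }
    return json.dumps(payload, indent=1)


def tree_from_json(text: str) -> FactorTree:
    payload = json.loads(text)
    tree = FactorTree()
    rng = payload.get("considered_range")
    tree.considered_range = tuple(rng) if rng else None
    for d in payload["factors"]:
        tree.add_factor(Factor(**d))
    return tree


def tree_to_dot(tree: FactorTree) -> str:
    """Graphviz DOT export of the factor linkage forest."""
    lines = ["digraph factor_tree {", "  rankdir=TB;"]
    for f in sorted(tree.factors.values(), key=lambda f: (f.K_tilde, f.column)):
        score = "" if f.score is None else f"\\n{f.score:.2f}"
        lines.append(f'  "{f.factor_id}" [label="{f.factor_id}{score}"];')
        if f.parent_id is not None:
            lines.append(f'  "{f.parent_id}" -> "{f.factor_id}";')
    lines.append("}")
    return "\n".join(lines)
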