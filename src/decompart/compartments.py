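"""Selection of final compartments from the factor tree.

Within the considered range of trial ranks, every root-to-leaf branch
of the linkage forest is scanned for *high-score blocks*: maximal runs
of adjacently linked factors whose scores exceed the median (Q2) of all
considered scores.  A branch yields at most one compartment:

* the branch must carry more than two considered factors;
* a block of three or more factors is a *major* candidate, a block of
  one or two an *unstable* candidate;
* the candidate factor is the block's score maximum and must itself
  exceed the third quartile (Q3) of all considered scores;
* among several qualifying blocks on one branch, the block with the
  most factors wins, ties broken by the greater block maximum.

A major largely duplicating another major on the same branch (more than
100 shared top-250 genes) is relabelled *minor*, keeping the one found
at the smaller rank as the representative.  Gene and sample weights of
the selected compartments are copied verbatim from their originating
runs, so the final W and H may mix columns from different ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    Compartment,
    CompartmentSet,
    Factor,
    FactorTree,
    ValidationError,
)

__all__ = [
    "score_quartiles",
    "branches",
    "identify_compartments",
    "label_minor",
    "assemble_final",
]

MINOR_OVERLAP = 100  # strict: relabel only when shared top genes exceed this


def _considered(tree: FactorTree) -> tuple[int, int]:
    if tree.considered_range is None:
        raise ValidationError("tree has no considered range; run the schedule first")
    return tree.considered_range


def score_quartiles(tree: FactorTree) -> tuple[float, float]:
    """Q2 and Q3 of all factor scores across the considered runs."""
    lo, hi = _considered(tree)
    scores = [
        f.score
        for f in tree.factors.values()
        if lo <= f.K_tilde <= hi and f.score is not None
    ]
    if not scores:
        raise ValidationError("no factor scores in the considered range")
    return float(np.quantile(scores, 0.5)), float(np.quantile(scores, 0.75))


def branches(tree: FactorTree) -> list[list[Factor]]:
    """Root-to-leaf paths of the linkage forest, ordered by leaf position.

    The rank-1 pseudo-factor (if present) is never part of a branch.
    """
    has_child = {f.parent_id for f in tree.factors.values() if f.parent_id}
    leaves = [
        f
        for f in tree.factors.values()
        if f.K_tilde >= 2 and f.factor_id not in has_child
    ]
    leaves.sort(key=lambda f: (f.K_tilde, f.column))
    out = []
    for leaf in leaves:
        path = [leaf]
        cur = leaf
        while cur.parent_id is not None:
            cur = tree.factors[cur.parent_id]
            if cur.K_tilde < 2:
                break
            path.append(cur)
        out.append(path[::-1])
    return out


@dataclass
class _Block:
    factors: list[Factor]

    @property
    def candidate(self) -> Factor:
        best = self.factors[0]
        for f in self.factors[1:]:
            if f.score > best.score:  # first max wins on ties (smaller rank)
                best = f
        return best

    @property
    def max_score(self) -> float:
        return max(f.score for f in self.factors)


def identify_compartments(tree: FactorTree) -> list[Compartment]:
    """Apply the branch/block selection rules and emit labelled compartments."""
    lo, hi = _considered(tree)
    q2, q3 = score_quartiles(tree)
    selected: list[Compartment] = []
    taken: set[str] = set()
    for branch in branches(tree):
        eligible = [
            f for f in branch if lo <= f.K_tilde <= hi and f.score is not None
        ]
        if len(eligible) <= 2:
            continue
        # maximal blocks of adjacently linked factors scoring above Q2
        blocks: list[_Block] = []
        current: list[Factor] = []
        for f in eligible:
            if f.score > q2:
                current.append(f)
            elif current:
                blocks.append(_Block(current))
                current = []
        if current:
            blocks.append(_Block(current))
        qualifying = [b for b in blocks if b.candidate.score > q3]
        if not qualifying:
            continue
        qualifying.sort(key=lambda b: (-len(b.factors), -b.max_score))
        winner = qualifying[0]
        cand = winner.candidate
        if cand.factor_id in taken:
            continue
        taken.add(cand.factor_id)
        label = "major" if len(winner.factors) >= 3 else "unstable"
        selected.append(
            Compartment(
                factor_id=cand.factor_id,
                label=label,
                K_tilde=cand.K_tilde,
                score=cand.score,
            )
        )
    if not selected:
        warnings.warn("no compartment satisfied the selection rules", stacklevel=2)
    return selected


def label_minor(selected: list[Compartment], tree: FactorTree) -> list[Compartment]:
    """Relabel majors that duplicate an earlier major on the same branch.

    Two majors are on the same linkage when one's factor is an ancestor
    of the other's; with more than 100 shared top-250 genes the one at
    the larger rank becomes *minor*.
    """
    majors = [c for c in selected if c.label == "major"]
    for i, a in enumerate(majors):
        for b in majors[i + 1:]:
            fa, fb = tree.factors[a.factor_id], tree.factors[b.factor_id]
            same_branch = tree.is_ancestor(a.factor_id, b.factor_id) or tree.is_ancestor(
                b.factor_id, a.factor_id
            )
            if not same_branch:
                continue
            overlap = len(set(fa.top250) & set(fb.top250))
            if overlap > MINOR_OVERLAP:
                later = a if fa.K_tilde > fb.K_tilde else b
                later.label = "minor"
    return selected


def assemble_final(
    selected: list[Compartment],
    tree: FactorTree,
    include_unstable: bool = False,
) -> CompartmentSet:
    """Extract the final W and H from the originating runs.

    Unstable compartments are reported in the listing but excluded from
    the weight matrices unless ``include_unstable`` is set.
    """
    if not selected:
        raise ValidationError("empty compartment selection")
    kept = [
        c for c in selected if include_unstable or c.label in ("major", "minor")
    ]
    if not kept:
        raise ValidationError("no major compartment to assemble (use "
                              "include_unstable to keep unstable ones)")
    ref = tree.runs[kept[0].K_tilde]
    W_cols, H_rows = [], []
    for c in kept:
        run = tree.runs[c.K_tilde]
        if run.feature_ids != ref.feature_ids or run.sample_ids != ref.sample_ids:
            raise ValidationError("runs disagree on feature/sample identifiers")
        col = tree.factors[c.factor_id].column
        W_cols.append(run.W_tilde[:, col])
        H_rows.append(run.H_tilde[col, :])
    return CompartmentSet(
        compartments=kept,
        W_final=np.column_stack(W_cols),
        H_final=np.vstack(H_rows),
        feature_ids=list(ref.feature_ids),
        sample_ids=list(ref.sample_ids),
    )
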