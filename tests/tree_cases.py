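"""Hand-constructed factor trees with hand-traced compartment selections.

Each case builds a linkage forest with explicit scores, sets the
considered rank range, and freezes the selection expected from tracing
the branch/block rules by hand: branches need more than two considered
factors; high-score blocks are maximal runs of factors scoring above
the median (Q2) of all considered scores; blocks of three or more
factors give majors, shorter blocks unstables; the block candidate is
its score maximum and must exceed the third quartile (Q3); the longest
block (ties: greatest maximum) wins per branch; majors on the same
branch sharing more than 100 top-250 genes demote the later one to
minor.
"""

from decompart.types import Factor, FactorTree


def _genes(tag: str, n: int = 250) -> list[str]:
    return [f"{tag}_g{i}" for i in range(n)]


def _shared_genes(tag_a: str, tag_b: str, n_shared: int) -> tuple[list, list]:
    shared = [f"{tag_a}{tag_b}_shared{i}" for i in range(n_shared)]
    a = shared + _genes(tag_a, 250 - n_shared)
    b = shared + _genes(tag_b, 250 - n_shared)
    return a, b


class TreeBuilder:
    def __init__(self):
        self.tree = FactorTree()
        self._cols: dict[int, int] = {}

    def factor(self, K, score, parent=None, top250=None, fid=None):
        col = self._cols.get(K, 0)
        self._cols[K] = col + 1
        fid = fid or f"{K}.{col + 1}"
        f = Factor(
            factor_id=fid,
            K_tilde=K,
            column=col,
            top250=top250 if top250 is not None else _genes(fid),
            score=score,
            parent_id=parent,
        )
        self.tree.add_factor(f)
        return fid

    def chain(self, start_K, scores, parent=None, top250s=None):
        """Linear chain of factors; returns the list of factor ids."""
        ids = []
        for i, s in enumerate(scores):
            top = top250s[i] if top250s else None
            parent = self.factor(start_K + i, s, parent, top)
            ids.append(parent)
        return ids

    def singletons(self, pairs):
        """Unlinked single factors (K, score) to shape the score pool."""
        for K, s in pairs:
            self.factor(K, s, parent=None)

    def done(self, considered):
        self.tree.considered_range = considered
        return self.tree


def case_single_major_simple():
    b = TreeBuilder()
    b.chain(2, [0.9, 0.85, 0.8, 0.3])
    b.singletons([(3, 0.5), (4, 0.45), (5, 0.4), (5, 0.35)])
    # Q2 = 0.475, Q3 = 0.8125; block [0.9, 0.85, 0.8] -> major at 2.1
    return b.done((2, 5)), {"2.1": "major"}


def case_short_branch_rejected():
    b = TreeBuilder()
    b.chain(2, [0.6, 0.7])
    b.singletons([(3, 0.2), (3, 0.3)])
    # branch carries only two factors -> no compartment
    return b.done((2, 3)), {}


def case_block_len1_unstable():
    b = TreeBuilder()
    b.chain(2, [0.3, 0.9, 0.3, 0.35])
    b.singletons([(3, 0.4), (4, 0.45), (5, 0.5)])
    # Q2 = 0.4, Q3 = 0.475; lone 0.9 factor -> unstable
    return b.done((2, 5)), {"3.1": "unstable"}


def case_block_len2_unstable():
    b = TreeBuilder()
    b.chain(2, [0.2, 0.8, 0.85, 0.3])
    b.singletons([(3, 0.4), (4, 0.45), (5, 0.5)])
    # Q2 = 0.45, Q3 = 0.65; block [0.8, 0.85] -> unstable at 4.1
    return b.done((2, 5)), {"4.1": "unstable"}


def case_block_len3_major():
    b = TreeBuilder()
    b.chain(2, [0.2, 0.8, 0.85, 0.8, 0.2])
    b.singletons([(3, 0.4), (4, 0.3), (5, 0.45), (6, 0.5)])
    # Q2 = 0.45, Q3 = 0.8; block [0.8, 0.85, 0.8] -> major at 4.1
    return b.done((2, 6)), {"4.1": "major"}


def case_candidate_below_q3():
    b = TreeBuilder()
    b.chain(2, [0.6, 0.65, 0.6, 0.2])
    b.singletons([(3, 0.9), (4, 0.95), (5, 0.85), (5, 0.2)])
    # Q2 = 0.625, Q3 = 0.8625; lone 0.65 block fails the Q3 rule
    return b.done((2, 5)), {}


def case_longer_block_wins():
    b = TreeBuilder()
    b.chain(2, [0.9, 0.85, 0.8, 0.2, 0.8, 0.85, 0.9, 0.95, 0.2])
    b.singletons(
        [(3, 0.3), (4, 0.35), (5, 0.4), (6, 0.45),
         (7, 0.3), (8, 0.35), (9, 0.4), (10, 0.45)]
    )
    # Q2 = 0.45, Q3 = 0.85; blocks of length 3 and 4 -> length 4 wins, 9.1
    return b.done((2, 10)), {"9.1": "major"}


def case_equal_length_greater_score_wins():
    b = TreeBuilder()
    b.chain(2, [0.85, 0.9, 0.85, 0.2, 0.85, 0.95, 0.85, 0.2])
    b.singletons([(3, 0.3), (4, 0.35), (5, 0.4), (6, 0.3), (7, 0.35), (8, 0.4)])
    # Q2 = 0.625, Q3 = 0.85; two length-3 blocks, maxima 0.9 vs 0.95 -> 7.1
    return b.done((2, 9)), {"7.1": "major"}


def case_branch_split_dedup():
    b = TreeBuilder()
    prefix = b.chain(2, [0.8, 0.85, 0.9])
    b.chain(5, [0.85, 0.8], parent=prefix[-1])   # branch A continues
    b.chain(5, [0.8, 0.3], parent=prefix[-1])    # branch B fades
    b.singletons([(4, 0.3), (5, 0.35), (6, 0.4), (6, 0.45)])
    # Q2 = 0.8, Q3 = 0.825; both branches select 4.1 -> emitted once
    return b.done((2, 6)), {"4.1": "major"}


def case_two_separate_majors():
    b = TreeBuilder()
    b.chain(2, [0.9, 0.85, 0.9, 0.2])
    b.chain(2, [0.85, 0.9, 0.85, 0.2])
    b.singletons([(4, 0.3), (4, 0.4), (5, 0.3), (5, 0.4)])
    # Q2 = 0.625, Q3 = 0.8625; one major per tree; ties at the block
    # maximum resolve to the smaller rank (2.1 over 4.1)
    return b.done((2, 5)), {"2.1": "major", "3.2": "major"}


def _split_tree_with_overlap(n_shared):
    b = TreeBuilder()
    top3, top7 = _shared_genes("A", "B", n_shared)
    prefix = b.chain(2, [0.85, 0.9, 0.85], top250s=[None, top3, None])
    # branch A: late length-4 block (its winner), candidate 7.1
    b.chain(5, [0.3, 0.85, 0.9, 0.85, 0.85, 0.3],
            parent=prefix[-1], top250s=[None, None, top7, None, None, None])
    # branch B fades right away
    b.chain(5, [0.3, 0.2], parent=prefix[-1])
    b.singletons([(3, 0.4), (4, 0.45), (5, 0.4), (6, 0.45)])
    return b


def case_minor_relabel_overlap_150():
    b = _split_tree_with_overlap(150)
    # majors 3.1 and 7.1 share one branch and 150 genes -> 7.1 demoted
    return b.done((2, 10)), {"3.1": "major", "7.1": "minor"}


def case_minor_boundary_overlap_100():
    b = _split_tree_with_overlap(100)
    # exactly 100 shared genes: strict rule, no demotion
    return b.done((2, 10)), {"3.1": "major", "7.1": "major"}


def case_no_minor_across_branches():
    b = TreeBuilder()
    ta, tb = _shared_genes("X", "Y", 200)
    b.chain(2, [0.9, 0.85, 0.9, 0.2], top250s=[ta, None, None, None])
    b.chain(2, [0.85, 0.9, 0.85, 0.2], top250s=[None, tb, None, None])
    b.singletons([(4, 0.3), (4, 0.4), (5, 0.3), (5, 0.4)])
    # 200 shared genes but disjoint linkages -> both stay major
    return b.done((2, 5)), {"2.1": "major", "3.2": "major"}


def case_newly_emerged_branch():
    b = TreeBuilder()
    b.chain(2, [0.85, 0.9, 0.85, 0.3])
    b.chain(4, [0.08, 0.9, 0.85, 0.9, 0.3])  # emerges at rank 4, no parent
    b.singletons([(3, 0.4), (4, 0.45), (5, 0.4)])
    # Q2 = 0.65, Q3 = 0.8625; emerged branch yields its own major
    # (candidate is the first of the tied 0.9 scores, at rank 5)
    return b.done((2, 8)), {"3.1": "major", "5.2": "major"}


def case_considered_range_excludes_early():
    b = TreeBuilder()
    b.chain(2, [0.9, 0.9, 0.85, 0.9, 0.85, 0.3])
    b.singletons([(3, 0.95), (5, 0.4), (6, 0.45), (7, 0.4)])
    # only ranks 4-7 considered: pool excludes the early 0.9s and the 0.95
    # singleton; Q2 = 0.45, Q3 = 0.85; block [4.1, 5.1, 6.1] -> major 5.1
    return b.done((4, 7)), {"5.1": "major"}


ALL_CASES = [
    case_single_major_simple,
    case_short_branch_rejected,
    case_block_len1_unstable,
    case_block_len2_unstable,
    case_block_len3_major,
    case_candidate_below_q3,
    case_longer_block_wins,
    case_equal_length_greater_score_wins,
    case_branch_split_dedup,
    case_two_separate_majors,
    case_minor_relabel_overlap_150,
    case_minor_boundary_overlap_100,
    case_no_minor_across_branches,
    case_newly_emerged_branch,
    case_considered_range_excludes_early,
]
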