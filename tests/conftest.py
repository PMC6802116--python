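import numpy as np
import pytest

from decompart.types import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """4x3 non-negative matrix with readable identifiers."""
    vals = np.array(
        [
            [1.0, 2.0, 3.0],
            [4.0, 5.0, 6.0],
            [0.5, 0.5, 0.5],
            [7.0, 0.0, 2.0],
        ]
    )
    return ExpressionMatrix(vals, ["g1", "g2", "g3", "g4"], ["s1", "s2", "s3"])


def brute_force_nnls(M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exhaustive active-set oracle for small NNLS problems.

    Solves the unconstrained least squares on every subset of columns,
    clips, and returns the feasible solution with the smallest residual.
    Exponential in the column count: use only for tiny problems.
    """
    from itertools import combinations

    n = M.shape[1]
    best_x, best_obj = np.zeros(n), np.linalg.norm(b)
    for k in range(1, n + 1):
        for cols in combinations(range(n), k):
            sub = M[:, cols]
            sol, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if np.any(sol < 0):
                continue
            x = np.zeros(n)
            x[list(cols)] = sol
            obj = np.linalg.norm(M @ x - b)
            if obj < best_obj - 1e-12:
                best_x, best_obj = x, obj
    return best_x
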