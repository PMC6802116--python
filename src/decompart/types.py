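"""Core containers for bulk-profile deconvolution.

The central objects mirror the matrices of the deconvolution model
``A ≈ W · H``: a non-negative features × samples input ``A``, gene
weights ``W`` (features × factors) and compartment weights ``H``
(factors × samples).  Factors produced at different trial ranks
(``K_tilde``) are organised into a :class:`FactorTree`, from which the
final :class:`CompartmentSet` is selected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "FilteredMatrix",
    "TrainingConfig",
    "FactorizationResult",
    "RunResult",
    "Factor",
    "FactorTree",
    "Compartment",
    "CompartmentSet",
    "MarkerList",
    "WeightEstimate",
    "SyntheticTruth",
    "ScheduleResult",
]


class ValidationError(ValueError):
    """Raised when an input matrix or configuration violates a contract."""


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for x in ids:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Non-negative features × samples matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n_features, n_samples)``; all entries must be
        finite and ≥ 0.
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("matrix must be two-dimensional")
        n, m = self.values.shape
        if n == 0 or m == 0:
            raise ValidationError("empty matrix")
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if len(self.feature_ids) != n or len(self.sample_ids) != m:
            raise ValidationError("identifier lengths do not match matrix shape")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[index],
            [self.feature_ids[i] for i in np.atleast_1d(index)],
            list(self.sample_ids),
        )


@dataclass
class FilteredMatrix(ExpressionMatrix):
    """Sub-matrix produced by a feature filter.

    ``provenance`` records the filter name and parameters so that
    re-applying the same filter is recognised as a no-op.
    """

    provenance: dict = field(default_factory=dict)


@dataclass
class TrainingConfig:
    """Configuration of the seed-training stage for one trial rank.

    ``R`` repetitions of ~80% column resampling are each factorised with
    ``n_inits`` random multiplicative-update starts of ``mult_steps``
    iterations, the best start refined by alternating least squares.  The
    top ``top_genes_consensus`` genes per factor feed a co-occurrence
    consensus matrix whose clusters seed the final factorisation with
    loadings ``seed_high`` (own cluster) / ``seed_low`` (elsewhere).
    """

    K_tilde: int = 2
    R: int = 10_000
    n_inits: int = 20
    mult_steps: int = 10
    resample_fraction: float = 0.8
    top_genes_consensus: int = 50
    seed_high: float = 1.0
    seed_low: float = 0.01
    rng_seed: int = 0
    als_tol: float = 1e-6
    als_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.K_tilde < 1:
            raise ValidationError("K_tilde must be >= 1")
        if not (0 < self.resample_fraction <= 1):
            raise ValidationError("resample_fraction must be in (0, 1]")
        if self.seed_low >= self.seed_high:
            raise ValidationError("seed_low must be < seed_high")

    def replace(self, **kw) -> "TrainingConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class FactorizationResult:
    """Output of the final seeded factorisation at one trial rank."""

    W_prime: np.ndarray  # filtered features x K_tilde
    H_prime: np.ndarray  # K_tilde x samples
    objective: float


@dataclass
class RunResult:
    """Definitive per-rank output after the two NNLS projections.

    ``W_tilde`` covers the *full* feature space of the input matrix so
    every gene obtains a weight; ``H_tilde`` covers all samples.
    """

    K_tilde: int
    factor_ids: list[str]
    W_tilde: np.ndarray  # full features x K_tilde
    H_tilde: np.ndarray  # K_tilde x samples
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.factor_ids) != self.W_tilde.shape[1]:
            raise ValidationError("factor_ids length must equal W_tilde columns")
        if self.W_tilde.shape[1] != self.H_tilde.shape[0]:
            raise ValidationError("W_tilde columns must equal H_tilde rows")


@dataclass
class Factor:
    """One factor from one run, scored against the previous rank."""

    factor_id: str
    K_tilde: int
    column: int  # column index within its run
    top250: list[str]
    score: Optional[float] = None
    parent_id: Optional[str] = None

    @property
    def is_newly_emerged(self) -> bool:
        return self.parent_id is None and self.score is not None


@dataclass
class ScheduleResult:
    """Outcome of the trial-rank schedule controller."""

    considered_start: int
    considered_end: int
    last_K: int
    capped: bool
    medians: dict[int, float]


@dataclass
class FactorTree:
    """Factors from all runs plus parent-child linkage across ranks."""

    runs: dict[int, RunResult] = field(default_factory=dict)
    factors: dict[str, Factor] = field(default_factory=dict)
    considered_range: Optional[tuple[int, int]] = None

    def add_factor(self, f: Factor) -> None:
        if f.factor_id in self.factors:
            raise ValidationError(f"duplicate factor id {f.factor_id!r}")
        self.factors[f.factor_id] = f

    def factors_at(self, K: int) -> list[Factor]:
        out = [f for f in self.factors.values() if f.K_tilde == K]
        out.sort(key=lambda f: f.column)
        return out

    def children_of(self, factor_id: str) -> list[Factor]:
        out = [f for f in self.factors.values() if f.parent_id == factor_id]
        out.sort(key=lambda f: (f.K_tilde, f.column))
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if factor ``a`` lies on the parent chain of factor ``b``."""
        cur = self.factors[b].parent_id
        while cur is not None:
            if cur == a:
                return True
            cur = self.factors[cur].parent_id
        return False


@dataclass
class Compartment:
    factor_id: str
    label: str  # major / minor / unstable
    K_tilde: int
    score: float
    annotation: str = ""

    @property
    def name(self) -> str:
        suffix = f":{self.annotation}" if self.annotation else ":"
        return f"D{self.factor_id}{suffix}"


@dataclass
class CompartmentSet:
    """Final selected compartments with assembled gene/sample weights.

    Columns of ``W_final`` (and rows of ``H_final``) are copied verbatim
    from the ``W_tilde``/``H_tilde`` of each compartment's originating
    run, so compartments may come from different trial ranks.
    """

    compartments: list[Compartment]
    W_final: np.ndarray  # features x K
    H_final: np.ndarray  # K x samples
    feature_ids: list[str]
    sample_ids: list[str]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)


@dataclass
class MarkerList:
    compartment_id: str
    markers: list[str]
    scores: np.ndarray  # normalized exclusive-weight score per marker


@dataclass
class WeightEstimate:
    """Per-sample compartment weights from NNLS projection onto saved W."""

    sample_id: str
    raw_weights: np.ndarray
    normalized_weights: Optional[np.ndarray] = None
    n_genes_used: int = 0
    all_zero: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated convex mixture ``A = W·H + noise``."""

    W_true: np.ndarray
    H_true: np.ndarray
    marker_blocks: dict[int, list[str]]  # compartment index -> marker feature ids
    feature_ids: list[str]
    sample_ids: list[str]
    noise_model: str
    rng_seed: int
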