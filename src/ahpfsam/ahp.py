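"""Modified analytic hierarchy process for quantitative gene ranking.

Classical AHP builds reciprocal pairwise-comparison matrices from expert
judgements on the discrete Saaty scale. Here the judgements are replaced
by a continuous map of the per-gene statistic differences onto [1, 10]:

    d_ij  = |c_i - c_j|
    c     = d_ij * 9 / c_max + 1        (c_max = max pairwise distance)
    x_ij  = c      if c_i >= c_j
            1 / c  otherwise

Each criterion's matrix yields a priority eigenvector by column-normalized
row averaging; the five eigenvectors are fused by a criterion-weight vector
(equal fifths by default) into one normalized gene priority.

A dense n x n matrix is materialized only for small n; above
``dense_limit`` the same quantities are streamed in blocks from the
closed-form element function, which is algebraically identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ranking import CRITERIA, GeneScoreTable, rank_genes

__all__ = [
    "PairwiseMatrix",
    "PriorityResult",
    "PerformanceMatrix",
    "pairwise_element",
    "build_pairwise_matrix",
    "priority_vector",
    "fuse_criteria",
    "select_genes_ahp",
    "random_index",
    "SCALE_SPAN",
]

# Superior elements live on [1, 10]: span 9 above the "equally important" 1.
SCALE_SPAN = 9.0

DENSE_LIMIT_DEFAULT = 2000

# Saaty's random index by matrix size, for the consistency ratio CI/RI.
_RI_TABLE = (0.0, 0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45,
             1.49, 1.51, 1.48, 1.56, 1.57, 1.59)  # index = n, up to n = 15

CR_WARN_THRESHOLD = 0.1


def random_index(n: int) -> float:
    """Expected CI of random reciprocal matrices of size n (Saaty's RI)."""
    if n <= 15:
        return _RI_TABLE[n]
    return 1.98 * (n - 2) / n


def pairwise_element(c_i: float, c_j: float, c_max: float) -> float:
    """Relative-importance ratio of item i over item j.

    Maps the score distance onto the continuous [1, 10] judgement scale
    (superior branch) or its reciprocal. ``c_max`` calibrates the scale:
    the most distant pair maps to exactly 10 (or 1/10).
    """
    if c_max < 0:
        raise ValueError("c_max must be nonnegative")
    d = abs(c_i - c_j)
    if c_max == 0:
        return 1.0
    if d > c_max * (1 + 1e-12):
        raise ValueError(
            f"distance {d} exceeds matrix calibration c_max={c_max}"
        )
    c = min(d, c_max) * SCALE_SPAN / c_max + 1.0
    return c if c_i >= c_j else 1.0 / c


@dataclass(frozen=True)
class PairwiseMatrix:
    """Reciprocal judgement matrix defined by a score vector.

    Elements are computed from ``scores`` and ``c_max`` on demand; for
    n <= dense_limit a dense backing array is materialized. +inf sentinel
    scores (from degenerate genes) are excluded from ``c_max`` and compare
    as absolutely more important (element 10) against any finite score.
    """

    scores: np.ndarray
    c_max: float
    dense_limit: int = DENSE_LIMIT_DEFAULT
    _dense: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def is_dense(self) -> bool:
        return self._dense is not None

    def element(self, i: int, j: int) -> float:
        if self._dense is not None:
            return float(self._dense[i, j])
        return _element_from_scores(
            self.scores[i], self.scores[j], self.c_max
        )

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorized sub-matrix for the streaming eigenvector path."""
        ci = self.scores[rows][:, None]
        cj = self.scores[cols][None, :]
        return _element_block(ci, cj, self.c_max)

    def dense(self) -> np.ndarray:
        if self._dense is not None:
            return self._dense
        idx = np.arange(self.n)
        return self.block(idx, idx)


def _element_from_scores(ci: float, cj: float, c_max: float) -> float:
    fi, fj = np.isfinite(ci), np.isfinite(cj)
    if not fi and not fj:
        return 1.0
    if not fi:
        return 10.0
    if not fj:
        return 0.1
    return pairwise_element(ci, cj, c_max)


def _element_block(ci: np.ndarray, cj: np.ndarray, c_max: float) -> np.ndarray:
    fi, fj = np.isfinite(ci), np.isfinite(cj)
    both = fi & fj
    if c_max == 0:
        c = np.ones(np.broadcast_shapes(ci.shape, cj.shape))
    else:
        with np.errstate(invalid="ignore"):
            d = np.abs(np.where(both, ci - cj, 0.0))
        c = d * SCALE_SPAN / c_max + 1.0
    with np.errstate(invalid="ignore"):
        sup = np.where(both, ci >= cj, True)
    x = np.where(sup, c, 1.0 / c)
    x = np.where(~fi & fj, 10.0, x)   # i is a +inf sentinel: absolute superior
    x = np.where(fi & ~fj, 0.1, x)
    x = np.where(~fi & ~fj, 1.0, x)
    return x


def build_pairwise_matrix(
    scores, dense_limit: int = DENSE_LIMIT_DEFAULT
) -> PairwiseMatrix:
    """Construct the judgement matrix for one criterion's score vector.

    ``c_max`` is the largest pairwise distance among finite scores, i.e.
    max(scores) - min(scores). All scores equal gives a matrix of ones
    (uniform priorities).
    """
    if isinstance(scores, GeneScoreTable):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two items for pairwise comparison")
    finite = scores[np.isfinite(scores)]
    c_max = float(finite.max() - finite.min()) if finite.size >= 2 else 0.0
    pm = PairwiseMatrix(scores=scores, c_max=c_max, dense_limit=dense_limit)
    if scores.size <= dense_limit:
        idx = np.arange(scores.size)
        dense = _element_block(scores[idx][:, None], scores[idx][None, :], c_max)
        object.__setattr__(pm, "_dense", dense)
    return pm


@dataclass(frozen=True)
class PriorityResult:
    """Priority eigenvector with per-row eigenvalues and consistency."""

    eigenvector: np.ndarray
    eigenvalues: np.ndarray
    lambda_max: float
    ci: float
    cr: float


def priority_vector(pm: PairwiseMatrix, block_size: int = 512) -> PriorityResult:
    """Column-normalized row-average priority vector with CI and CR.

    S_j = sum_i x_ij; eps_i = (1/n) sum_j x_ij / S_j; lambda_i =
    (row_i . eps) / eps_i. CI = (lambda_max - n)/(n - 1), CR = CI/RI(n).
    The streaming path visits the matrix in blocks and never materializes
    it; it is exactly the dense arithmetic reordered.
    """
    n = pm.n
    if n == 1:
        one = np.ones(1)
        return PriorityResult(one, one, 1.0, 0.0, 0.0)

    if pm.is_dense:
        x = pm.dense()
        col_sums = x.sum(axis=0)
        eps = (x / col_sums).sum(axis=1) / n
        row_dot = x @ eps
    else:
        idx = np.arange(n)
        col_sums = np.zeros(n)
        for start in range(0, n, block_size):
            rows = idx[start:start + block_size]
            col_sums += pm.block(rows, idx).sum(axis=0)
        eps = np.zeros(n)
        row_dot = np.zeros(n)
        for start in range(0, n, block_size):
            rows = idx[start:start + block_size]
            eps[rows] = (pm.block(rows, idx) / col_sums).sum(axis=1) / n
        # eps must be complete before the row dot products
        for start in range(0, n, block_size):
            rows = idx[start:start + block_size]
            row_dot[rows] = pm.block(rows, idx) @ eps

    lam = row_dot / eps
    lambda_max = float(lam.max())
    ci = (lambda_max - n) / (n - 1)
    ri = random_index(n)
    cr = ci / ri if ri > 0 else 0.0
    return PriorityResult(eps, lam, lambda_max, float(ci), float(cr))


@dataclass(frozen=True)
class PerformanceMatrix:
    """Per-criterion priority eigenvectors stacked genes × criteria."""

    eigenvectors: np.ndarray  # shape (n_genes, n_criteria)
    criteria: tuple[str, ...] = CRITERIA
    weights: np.ndarray | None = None

    def __post_init__(self):
        ev = np.asarray(self.eigenvectors, dtype=float)
        object.__setattr__(self, "eigenvectors", ev)
        w = self.weights
        if w is None:
            w = np.full(ev.shape[1], 1.0 / ev.shape[1])
        w = np.asarray(w, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.size != ev.shape[1]:
            raise ValueError("one weight per criterion required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")


def fuse_criteria(pm: PerformanceMatrix) -> np.ndarray:
    """Weighted fusion of the per-criterion priorities: P @ w.

    Requires each eigenvector column to sum to 1; the fused priority is
    then automatically normalized.
    """
    col = pm.eigenvectors.sum(axis=0)
    if not np.allclose(col, 1.0, atol=1e-6):
        raise ValueError(f"eigenvector columns must each sum to 1, got {col}")
    return pm.eigenvectors @ pm.weights


@dataclass(frozen=True)
class AhpSelection:
    """Top-k gene choice with the full fused priority and CR diagnostics."""

    selected_gene_ids: list[str]
    selected_index: np.ndarray
    priorities: np.ndarray
    per_criterion: dict[str, PriorityResult]
    c_max: dict[str, float]


def select_genes_ahp(
    ds,
    k: int,
    weights=None,
    criteria: tuple[str, ...] = CRITERIA,
    dense_limit: int = DENSE_LIMIT_DEFAULT,
) -> AhpSelection:
    """Rank genes under all five criteria, fuse via modified AHP, take top k.

    Emits a warning for any criterion whose consistency ratio exceeds the
    conventional 0.1 threshold (diagnostic only; the continuous judgement
    scale usually keeps CR well below it).
    """
    if k > ds.n_genes:
        raise ValueError(f"k={k} exceeds gene count {ds.n_genes}")
    results: dict[str, PriorityResult] = {}
    cmaxes: dict[str, float] = {}
    columns = []
    for crit in criteria:
        table = rank_genes(ds, crit)
        pm = build_pairwise_matrix(table.scores, dense_limit=dense_limit)
        pr = priority_vector(pm)
        if pr.cr > CR_WARN_THRESHOLD:
            warnings.warn(
                f"criterion {crit!r}: consistency ratio {pr.cr:.3f} "
                f"exceeds {CR_WARN_THRESHOLD}",
                stacklevel=2,
            )
        results[crit] = pr
        cmaxes[crit] = pm.c_max
        columns.append(pr.eigenvector)
    perf = PerformanceMatrix(
        eigenvectors=np.column_stack(columns),
        criteria=tuple(criteria),
        weights=weights,
    )
    fused = fuse_criteria(perf)
    order = np.lexsort((np.arange(fused.size), -fused))
    top = order[:k]
    return AhpSelection(
        selected_gene_ids=[ds.gene_ids[i] for i in top],
        selected_index=top,
        priorities=fused,
        per_criterion=results,
        c_max=cmaxes,
    )
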