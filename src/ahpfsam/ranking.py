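"""Per-gene filter statistics: t-test, relative entropy, ROC, Wilcoxon, SNR.

All five criteria are direction-free scores (higher = more informative) so
they can feed the pairwise-comparison stage on a common footing:

* ``ttest``    |t| with the Welch denominator sqrt(s1^2/n1 + s2^2/n2)
* ``entropy``  symmetric Kullback–Leibler divergence between the two
  Gaussian class-conditional models of the gene
* ``roc``      |AUC - 1/2|, the area between the empirical ROC curve and
  the diagonal (midrank tie handling)
* ``wilcoxon`` |z| of the rank sum of the smaller class, tie-corrected
* ``snr``      |mu1 - mu2| / (s1 + s2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "CRITERIA",
    "ClassSummary",
    "GeneScoreTable",
    "summarize_classes",
    "score_ttest",
    "score_entropy",
    "score_roc",
    "score_wilcoxon",
    "score_snr",
    "auc_mann_whitney",
    "rank_genes",
]

CRITERIA = ("ttest", "entropy", "roc", "wilcoxon", "snr")

# Relative floor applied to class variances so constant genes score
# deterministically instead of dividing by zero.
VARIANCE_FLOOR_FRACTION = 1e-8


@dataclass(frozen=True)
class ClassSummary:
    """Per-class first and second moments of one gene's expression."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                f"each class needs >=2 samples (n1={self.n1}, n2={self.n2})"
            )
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class GeneScoreTable:
    """Scores for one criterion plus the descending-score gene order."""

    criterion: str
    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "order", np.asarray(self.order, dtype=int))
        if self.scores.shape != self.order.shape:
            raise ValueError("scores and order must have equal length")


def summarize_classes(values, labels) -> ClassSummary:
    """Class means and n−1 standard deviations for one gene."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v1, v2 = values[labels == 0], values[labels == 1]
    if v1.size < 2 or v2.size < 2:
        raise ValueError(
            f"each class needs >=2 samples (got {v1.size} and {v2.size})"
        )
    return ClassSummary(
        mu1=float(v1.mean()),
        mu2=float(v2.mean()),
        sigma1=float(v1.std(ddof=1)),
        sigma2=float(v2.std(ddof=1)),
        n1=v1.size,
        n2=v2.size,
    )


def _floored_vars(s: ClassSummary) -> tuple[float, float]:
    pooled = (s.sigma1**2 * (s.n1 - 1) + s.sigma2**2 * (s.n2 - 1)) / (
        s.n1 + s.n2 - 2
    )
    floor = VARIANCE_FLOOR_FRACTION * max(pooled, 1.0)
    return max(s.sigma1**2, floor), max(s.sigma2**2, floor)


def score_ttest(s: ClassSummary) -> float:
    """|t| with the Welch (unequal-variance) standard error."""
    diff = s.mu1 - s.mu2
    if s.sigma1 == 0 and s.sigma2 == 0:
        return 0.0 if diff == 0 else np.inf
    v1, v2 = _floored_vars(s)
    return abs(diff) / np.sqrt(v1 / s.n1 + v2 / s.n2)


def score_entropy(s: ClassSummary) -> float:
    """Symmetric KL divergence of the two Gaussian class models; >= 0."""
    if s.sigma1 == 0 and s.sigma2 == 0:
        return 0.0 if s.mu1 == s.mu2 else np.inf
    v1, v2 = _floored_vars(s)
    diff2 = (s.mu1 - s.mu2) ** 2
    return 0.5 * ((v1 / v2 + v2 / v1 - 2.0) + (1.0 / v1 + 1.0 / v2) * diff2)


def score_snr(s: ClassSummary) -> float:
    """Class separation |mu1 - mu2| / (sigma1 + sigma2)."""
    diff = abs(s.mu1 - s.mu2)
    if s.sigma1 + s.sigma2 == 0:
        return 0.0 if diff == 0 else np.inf
    v1, v2 = _floored_vars(s)
    return diff / (np.sqrt(v1) + np.sqrt(v2))


def auc_mann_whitney(values, labels) -> float:
    """Empirical AUC (P[class-1 value > class-0 value]) by the rank formula.

    Midranks handle ties; equals brute-force counting of between-class
    pairs with ties counted 1/2.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(np.sum(labels == 1))
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be nonempty for AUC")
    ranks = rankdata(values, method="average")
    r1 = ranks[labels == 1].sum()
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def score_roc(values, labels) -> float:
    """Area between the empirical ROC curve and the diagonal: |AUC - 1/2|."""
    return abs(auc_mann_whitney(values, labels) - 0.5)


def score_wilcoxon(values, labels) -> float:
    """|z| of the rank sum W of the smaller class, with tie correction.

    W is the sum of midranks of the smaller class (class 0 on equal sizes;
    |z| does not depend on the choice). z = (W - mu_W)/sigma_W with
    mu_W = n_s(n_s + n_l + 1)/2 and the tie-corrected sigma_W.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n0 = int(np.sum(labels == 0))
    n1 = labels.size - n0
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be nonempty")
    small = 0 if n0 <= n1 else 1
    ns = n0 if small == 0 else n1
    nl = labels.size - ns

    ranks = rankdata(values, method="average")
    w = ranks[labels == small].sum()
    mu_w = ns * (ns + nl + 1) / 2.0

    n = labels.size
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0))
    var_w = ns * nl / 12.0 * ((n + 1.0) - tie_term)
    if var_w <= 0:
        return 0.0
    return abs(w - mu_w) / np.sqrt(var_w)


_SUMMARY_SCORERS = {
    "ttest": score_ttest,
    "entropy": score_entropy,
    "snr": score_snr,
}
_SAMPLE_SCORERS = {"roc": score_roc, "wilcoxon": score_wilcoxon}


def score_gene(values, labels, criterion: str) -> float:
    """Apply one criterion's scorer to a single gene profile."""
    if criterion in _SUMMARY_SCORERS:
        return _SUMMARY_SCORERS[criterion](summarize_classes(values, labels))
    if criterion in _SAMPLE_SCORERS:
        return _SAMPLE_SCORERS[criterion](values, labels)
    raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


def rank_genes(ds, criterion: str) -> GeneScoreTable:
    """Score every gene under one criterion and sort by descending score.

    Ties (and any +inf sentinels from degenerate genes) are broken by
    ascending gene index, making the order deterministic.
    """
    ds.require_two_classes()
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    scores = np.empty(ds.n_genes)
    for i in range(ds.n_genes):
        try:
            scores[i] = score_gene(ds.matrix[i], ds.labels, criterion)
        except ValueError as err:
            raise ValueError(
                f"gene {ds.gene_ids[i]!r}: {err}"
            ) from err
    # stable sort on negated finite keys; +inf ranks first
    order = np.lexsort((np.arange(scores.size), -scores))
    return GeneScoreTable(criterion=criterion, scores=scores, order=order)
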