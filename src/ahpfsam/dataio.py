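"""Expression-matrix I/O, pre-filtering and quantile normalization.

The container is a genes × samples matrix (genes as rows, the usual
orientation for microarray studies with thousands of genes and tens of
samples) with a binary class label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionDataset",
    "FilterConfig",
    "read_expression",
    "write_expression",
    "quantile_normalize",
    "prefilter_genes",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Two-class expression data: real-valued matrix, IDs and 0/1 labels.

    Parameters
    ----------
    matrix : ndarray, shape (n_genes, n_samples)
        Expression intensities; genes are rows.
    gene_ids, sample_ids : list of str
        Unique identifiers for rows and columns.
    labels : ndarray of int, shape (n_samples,)
        Class membership coded 0/1.
    label_mapping : dict
        Original label value → {0, 1} code, recorded at load time.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", lab)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x samples)")
        if m.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"matrix has {m.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if m.shape[1] != len(self.sample_ids) or m.shape[1] != lab.size:
            raise ValueError("sample ids / labels do not match matrix columns")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not set(np.unique(lab)).issubset({0, 1}):
            raise ValueError("labels must be coded 0/1")
        if np.isnan(m).any():
            raise ValueError("matrix contains NaN after loading")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def require_two_classes(self) -> None:
        """Scoring needs at least two samples in each class."""
        n0, n1 = self.class_counts()
        if n0 < 2 or n1 < 2:
            raise ValueError(
                f"both classes need >=2 samples (got n0={n0}, n1={n1})"
            )

    def subset_genes(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return replace(
            self,
            matrix=self.matrix[index],
            gene_ids=[self.gene_ids[i] for i in index],
        )

    def subset_samples(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return replace(
            self,
            matrix=self.matrix[:, index],
            sample_ids=[self.sample_ids[i] for i in index],
            labels=self.labels[index],
        )


@dataclass(frozen=True)
class FilterConfig:
    """Percentile thresholds for the four gene pre-filters.

    A gene is removed when its statistic (max |value|, variance, max−min
    range, or histogram entropy) falls below the given percentile of that
    statistic over all genes. A percentile of ``None`` disables the filter.
    Defaults: all filters off; 0.10 is the conventional setting when enabled.
    """

    low_value_percentile: float | None = None
    low_variance_percentile: float | None = None
    low_range_percentile: float | None = None
    low_entropy_percentile: float | None = None
    entropy_bins: int = 10

    def __post_init__(self):
        for name in (
            "low_value_percentile",
            "low_variance_percentile",
            "low_range_percentile",
            "low_entropy_percentile",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(
    matrix_path,
    labels_path,
    sep: str = "\t",
    transpose: bool = False,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Load a delimited expression matrix and a sample→label table.

    The matrix file has one header row of sample IDs and gene IDs in the
    first column. The labels file is two-column (sample_id, label) with a
    header; exactly two distinct label values are allowed and are recoded
    to {0, 1} in sorted order of their string representation.

    Missing cells are rejected unless ``impute_missing`` is set, in which
    case they are replaced by the per-gene median.
    """
    df = pd.read_csv(matrix_path, sep=sep, index_col=0,
                     float_precision="round_trip")
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]

    lab_df = pd.read_csv(labels_path, sep=sep)
    if lab_df.shape[1] < 2:
        raise ValueError("labels file needs two columns: sample_id, label")
    lab_map = {str(r[0]): r[1] for r in lab_df.itertuples(index=False)}

    missing = [s for s in sample_ids if s not in lab_map]
    extra = [s for s in lab_map if s not in set(sample_ids)]
    if missing or extra:
        raise ValueError(
            "sample ID mismatch between matrix and labels; "
            f"unlabelled: {missing}; unmatched in labels: {extra}"
        )

    raw = [lab_map[s] for s in sample_ids]
    classes = sorted({str(v) for v in raw})
    if len(classes) != 2:
        raise ValueError(
            f"exactly two distinct labels required, got {classes}"
        )
    mapping = {classes[0]: 0, classes[1]: 1}
    labels = np.array([mapping[str(v)] for v in raw], dtype=int)

    matrix = df.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        if not impute_missing:
            bad = np.where(np.isnan(matrix).any(axis=1))[0]
            names = [gene_ids[i] for i in bad[:5]]
            raise ValueError(
                f"missing values in genes {names}; "
                "pass impute_missing=True for per-gene median imputation"
            )
        med = np.nanmedian(matrix, axis=1, keepdims=True)
        matrix = np.where(np.isnan(matrix), med, matrix)

    return ExpressionDataset(matrix, gene_ids, sample_ids, labels, mapping)


def write_expression(ds: ExpressionDataset, matrix_path, labels_path, sep="\t"):
    """Write a dataset back to the two-file delimited layout."""
    pd.DataFrame(
        ds.matrix, index=ds.gene_ids, columns=ds.sample_ids
    ).to_csv(matrix_path, sep=sep, index_label="gene_id")
    pd.DataFrame(
        {"sample_id": ds.sample_ids, "label": ds.labels}
    ).to_csv(labels_path, sep=sep, index=False)


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample (column) onto the mean order-statistic distribution.

    After normalization the sorted values of all columns are identical: the
    value at rank r is the across-column mean of the r-th order statistics.
    Ties within a column receive the mean of the normalized values at their
    tied ranks, so the map is deterministic and symmetric.
    """
    if ds.n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    x = ds.matrix
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        # average ranks are 1-based and possibly half-integer under ties
        r = rankdata(x[:, j], method="average") - 1.0
        lo = np.floor(r).astype(int)
        hi = np.ceil(r).astype(int)
        out[:, j] = 0.5 * (mean_sorted[lo] + mean_sorted[hi])
    return replace(ds, matrix=out)


_FILTERS = ("low_value", "low_variance", "low_range", "low_entropy")


def _gene_statistics(matrix: np.ndarray, bins: int) -> dict[str, np.ndarray]:
    stats = {
        "low_value": np.abs(matrix).max(axis=1),
        "low_variance": matrix.var(axis=1, ddof=1),
        "low_range": matrix.max(axis=1) - matrix.min(axis=1),
    }
    ent = np.empty(matrix.shape[0])
    for i, row in enumerate(matrix):
        counts, _ = np.histogram(row, bins=bins)
        p = counts[counts > 0] / counts.sum()
        ent[i] = -np.sum(p * np.log(p))
    stats["low_entropy"] = ent
    return stats


def prefilter_genes(
    ds: ExpressionDataset, cfg: FilterConfig
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Drop genes with low absolute values, little variation, small profile
    ranges or low entropy.

    Each enabled filter removes genes whose statistic lies strictly below
    the configured percentile of that statistic across all genes. Returns
    the filtered dataset and a removal log (gene_id, failed_filter).
    """
    stats = _gene_statistics(ds.matrix, cfg.entropy_bins)
    thresholds = {}
    for name in _FILTERS:
        pct = getattr(cfg, name + "_percentile")
        if pct is not None and pct > 0:
            thresholds[name] = np.quantile(stats[name], pct)

    failed: list[tuple[str, str]] = []
    keep = np.ones(ds.n_genes, dtype=bool)
    for name, thr in thresholds.items():
        below = stats[name] < thr
        for i in np.where(below & keep)[0]:
            failed.append((ds.gene_ids[i], name))
        keep &= ~below

    if not keep.any():
        raise ValueError(
            "all genes removed by pre-filtering; relax the percentile thresholds"
        )
    log = pd.DataFrame(failed, columns=["gene_id", "failed_filter"])
    return ds.subset_genes(np.where(keep)[0]), log
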