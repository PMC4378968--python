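"""Leave-one-out cross-validation of the select → train → classify pipeline.

Every sample is held out once; the remaining K−1 samples drive gene
selection (per-fold by default, so the held-out sample never influences
which genes are used), fuzzy c-means + GA structure learning, and gradient
tuning. LOOCV accuracy is the exact fraction of correctly classified
folds; sensitivity, specificity and the rank-based AUC of the continuous
scores complete the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ahp import select_genes_ahp
from .dataio import ExpressionDataset
from .fsam import TrainConfig, classify, train_supervised
from .ga import GAConfig, evolve
from .ranking import CRITERIA, auc_mann_whitney, rank_genes

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "confusion_metrics",
    "auc_scores",
    "loocv",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of one end-to-end run: selection method + learner settings.

    selection: "ahp" or one of the five single criteria.
    selection_scope: "per_fold" recomputes gene selection inside each
    training fold (no leakage); "full_data" selects once on all samples,
    as is common in the microarray literature.
    """

    n_genes: int = 10
    selection: str = "ahp"
    selection_scope: str = "per_fold"
    criterion_weights: tuple | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    master_seed: int = 0

    def __post_init__(self):
        if self.selection not in ("ahp",) + CRITERIA:
            raise ValueError(f"unknown selection method {self.selection!r}")
        if self.selection_scope not in ("per_fold", "full_data"):
            raise ValueError("selection_scope must be per_fold or full_data")


@dataclass(frozen=True)
class EvaluationReport:
    loocv_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_fold: list  # (sample_id, true, predicted, score)
    n_folds: int
    config: PipelineConfig


def confusion_metrics(true_labels, predicted_labels, positive=1):
    """(accuracy, sensitivity, specificity) from aligned 0/1 label vectors.

    A class absent from the truth makes the corresponding rate undefined
    (returned as NaN, not 0).
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must be aligned")
    pos = t == positive
    neg = ~pos
    tp = int(np.sum(pos & (p == positive)))
    tn = int(np.sum(neg & (p != positive)))
    accuracy = (tp + tn) / t.size
    sensitivity = tp / pos.sum() if pos.any() else UNDEFINED
    specificity = tn / neg.sum() if neg.any() else UNDEFINED
    return accuracy, sensitivity, specificity


def auc_scores(true_labels, scores) -> float:
    """Empirical rank-based AUC of continuous scores (midrank ties)."""
    t = np.asarray(true_labels, dtype=int)
    if len(set(t.tolist())) < 2:
        return UNDEFINED
    return auc_mann_whitney(np.asarray(scores, dtype=float), t)


def _select(ds: ExpressionDataset, cfg: PipelineConfig) -> np.ndarray:
    if cfg.selection == "ahp":
        sel = select_genes_ahp(ds, cfg.n_genes, weights=cfg.criterion_weights)
        return sel.selected_index
    table = rank_genes(ds, cfg.selection)
    return table.order[: cfg.n_genes]


def _standardize(train_x, test_x):
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_x - mu) / sd, (test_x - mu) / sd


def _train_and_predict(train_x, train_y, test_x, cfg: PipelineConfig, seed):
    ga_cfg = GAConfig(**{**cfg.ga.__dict__, "seed": int(seed)})
    result = evolve(train_x, train_y, ga_cfg)
    tr_cfg = TrainConfig(**{**cfg.train.__dict__, "seed": int(seed) + 1})
    model, _ = train_supervised(result.best_model, train_x, train_y, tr_cfg)
    return classify(model, test_x)


def loocv(ds: ExpressionDataset, cfg: PipelineConfig) -> EvaluationReport:
    """Leave-one-out evaluation of the full pipeline.

    Folds are processed with per-fold derived seeds (master_seed, fold),
    so any execution order yields identical output. A fold whose training
    portion loses one class entirely is skipped with a warning and
    excluded from K.
    """
    ds.require_two_classes()
    k = ds.n_samples
    if k < 3:
        raise ValueError("LOOCV needs at least 3 samples")

    full_selection = None
    if cfg.selection_scope == "full_data":
        full_selection = _select(ds, cfg)

    per_fold = []
    for fold in range(k):
        train_mask = np.ones(k, dtype=bool)
        train_mask[fold] = False
        train_ds = ds.subset_samples(np.where(train_mask)[0])
        if len(set(train_ds.labels.tolist())) < 2:
            warnings.warn(f"fold {fold}: training portion lost a class; skipped")
            continue
        genes = (
            full_selection
            if full_selection is not None
            else _select(train_ds, cfg)
        )
        train_x = train_ds.matrix[genes].T  # samples x genes
        test_x = ds.matrix[genes, fold]
        train_x, test_x = _standardize(train_x, test_x)
        seed = int(
            np.random.SeedSequence([cfg.master_seed, fold]).generate_state(1)[0]
            % (2**31 - 1)
        )
        label, score = _train_and_predict(
            train_x, train_ds.labels.astype(float), test_x, cfg, seed
        )
        per_fold.append((ds.sample_ids[fold], int(ds.labels[fold]), label, score))

    n_folds = len(per_fold)
    true = [r[1] for r in per_fold]
    pred = [r[2] for r in per_fold]
    scores = [r[3] for r in per_fold]
    correct = sum(t == p for t, p in zip(true, pred))
    accuracy = correct / n_folds
    _, sens, spec = confusion_metrics(true, pred)
    return EvaluationReport(
        loocv_accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        auc=auc_scores(true, scores),
        per_fold=per_fold,
        n_folds=n_folds,
        config=cfg,
    )
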