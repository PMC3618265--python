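"""Cross-validated evaluation: ROC/PR curves, confusion summaries,
Ki-threshold sweeps, Ki-vs-probability correlation and property ablation.

Five-fold stratified cross-validation pools out-of-fold probabilities so
that every drug-target pair is predicted exactly once by a model that
never saw it.  Classifier quality is summarized by the area under the
ROC curve (auROC, trapezoidal) and the area under the precision-recall
curve (auPRC, computed as average precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve
from sklearn.model_selection import StratifiedKFold, KFold

from dtiscreen.classifier import DEFAULT_NTREE, predict_proba, train_rf
from dtiscreen.protein import INDEX_MAP
from dtiscreen.fingerprints import N_FINGERPRINT_BITS


@dataclass
class CVResult:
    """Pooled out-of-fold predictions from k-fold cross-validation."""

    proba: np.ndarray
    labels: np.ndarray
    fold: np.ndarray
    median_ki_nM: np.ndarray | None = None


@dataclass(frozen=True)
class ConfusionSummary:
    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    @property
    def Sen(self) -> float:
        return self.TP * 100.0 / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def Spe(self) -> float:
        return self.TN * 100.0 / (self.TN + self.FP) if self.TN + self.FP else float("nan")

    @property
    def Acc(self) -> float:
        return (self.TP + self.TN) * 100.0 / self.n


@dataclass(frozen=True)
class CurveSummary:
    roc_points: np.ndarray  # (FPR, TPR) rows
    pr_points: np.ndarray   # (recall, precision) rows
    auroc: float
    auprc: float


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
    ntree: int = DEFAULT_NTREE,
    mtry: int | None = None,
    median_ki_nM: np.ndarray | None = None,
    train_fn=None,
) -> CVResult:
    """k-fold cross-validation with pooled out-of-fold probabilities.

    Folds are stratified by label (sizes differ by at most one) and
    fixed by ``seed``; each fold is predicted by a model trained on the
    other k-1 folds.  ``train_fn(X, y, seed) -> model with
    predict_proba`` overrides the default random-forest trainer.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    proba = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    rng = np.random.default_rng(seed)
    for fold_idx, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold_seed = int(rng.integers(2**31))
        if train_fn is not None:
            model = train_fn(X[train_idx], y[train_idx], fold_seed)
            proba[test_idx] = model.predict_proba(X[test_idx])
        else:
            model = train_rf(X[train_idx], y[train_idx], mtry=mtry, ntree=ntree, seed=fold_seed)
            proba[test_idx] = predict_proba(model, X[test_idx])
        fold_of[test_idx] = fold_idx
    return CVResult(proba=proba, labels=y, fold=fold_of, median_ki_nM=median_ki_nM)


def curves_and_areas(scores: np.ndarray, labels: np.ndarray) -> CurveSummary:
    """ROC and precision-recall curves with their areas.

    auROC is trapezoidal; auPRC is average precision (the step-wise
    integral of the PR curve).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("curve areas require both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return CurveSummary(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall[::-1], precision[::-1]]),
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
    )


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionSummary:
    """Confusion counts with a score >= threshold predicted positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionSummary(
        TP=int((pred & pos).sum()),
        FN=int((~pred & pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FP=int((pred & ~pos).sum()),
    )


def threshold_sweep(
    records: pd.DataFrame,
    fingerprints: dict,
    protein_vectors: dict,
    thresholds_uM: tuple[float, ...] = tuple(range(10, 91, 5)),
    k: int = 5,
    seed: int = 0,
    ntree: int = DEFAULT_NTREE,
) -> pd.DataFrame:
    """Relabel the Ki table at each threshold and cross-validate.

    Returns one row per threshold with auROC/auPRC and class counts; a
    threshold leaving a single class is skipped with a warning row
    (NaN metrics).
    """
    import logging

    from dtiscreen.pairs import build_pair_dataset, label_pairs

    logger = logging.getLogger(__name__)
    rows = []
    for t_uM in thresholds_uM:
        if t_uM <= 0:
            raise ValueError("Ki thresholds must be positive")
        labeled = label_pairs(records, threshold_nM=t_uM * 1000.0)
        n_pos = int(labeled["label"].sum())
        if n_pos == 0 or n_pos == len(labeled):
            logger.warning("threshold %s uM yields a single class; skipped", t_uM)
            rows.append({"threshold_uM": t_uM, "n_pos": n_pos, "n": len(labeled),
                         "auroc": np.nan, "auprc": np.nan})
            continue
        X, y, _ = build_pair_dataset(labeled, fingerprints, protein_vectors)
        cv = kfold_cv(X, y, k=k, seed=seed, ntree=ntree)
        summary = curves_and_areas(cv.proba, cv.labels)
        rows.append({"threshold_uM": t_uM, "n_pos": n_pos, "n": len(labeled),
                     "auroc": summary.auroc, "auprc": summary.auprc})
    return pd.DataFrame(rows)


def ki_probability_correlation(median_ki_nM: np.ndarray, probabilities: np.ndarray) -> float:
    """Pearson correlation of log10(Ki) against predicted probability.

    The signed value is returned as computed: a negative r means high
    predicted interaction probability goes with low (tight-binding) Ki.
    """
    ki = np.asarray(median_ki_nM, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if (ki <= 0).any():
        raise ValueError("Ki values must be positive")
    log_ki = np.log10(ki)
    if np.std(log_ki) == 0 or np.std(p) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(log_ki, p).statistic)


def ablate_property(
    X: np.ndarray, property_id: str
) -> tuple[np.ndarray, list[int]]:
    """Remove one protein property's descriptor columns from a pair matrix.

    ``property_id`` is one of the seven CTD property names (21 columns
    each) or ``"aac"`` (20 columns).  Returns the reduced matrix and the
    removed column indices (in full-matrix coordinates).
    """
    if property_id not in INDEX_MAP:
        raise KeyError(f"unknown property {property_id!r}; choose from {sorted(INDEX_MAP)}")
    X = np.asarray(X)
    sl = INDEX_MAP[property_id]
    removed = list(range(N_FINGERPRINT_BITS + sl.start, N_FINGERPRINT_BITS + sl.stop))
    keep = [i for i in range(X.shape[1]) if i not in set(removed)]
    return X[:, keep], removed
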