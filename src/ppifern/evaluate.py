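"""Confusion-matrix metrics, ROC/AUC and the 5-fold cross-validation protocol.

Metrics follow the standard binary-classification definitions with the
positive class = 1:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SN  = TP / (TP + FN)
    PE  = TP / (TP + FP)
    MCC = (TN*TP - FN*FP) / sqrt((TP+FP)(TN+FP)(TN+FN)(FN+TP))

Any metric whose denominator is zero is reported as 0, so reports are
always total.  AUC uses the rank-based (Mann-Whitney) formulation: the
fraction of (positive, negative) score pairs ranked concordantly, ties
counted one half.  Cross-validation retrains the whole pipeline (SDAE
included) inside each fold so no information from a held-out fold leaks
into training; folds are stratified by label by default and the summary
reports mean and sample standard deviation (k-1 denominator) across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import PairTable, PSSMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    sn: float
    pe: float
    mcc: float
    auc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sn": self.sn,
            "pe": self.pe,
            "mcc": self.mcc,
            "auc": self.auc,
            "counts": self.counts.to_dict(),
        }


METRIC_NAMES = ("acc", "sn", "pe", "mcc", "auc")


@dataclass
class CVReport:
    per_fold: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_fold and not self.mean:
            values = {
                m: np.array([getattr(r, m) for r in self.per_fold])
                for m in METRIC_NAMES
            }
            self.mean = {m: float(v.mean()) for m, v in values.items()}
            # Sample standard deviation across the k held-out folds.
            self.std = {
                m: float(v.std(ddof=1)) if len(v) > 1 else 0.0
                for m, v in values.items()
            }

    def to_dict(self) -> dict:
        return {
            "per_fold": [r.to_dict() for r in self.per_fold],
            "mean": self.mean,
            "std": self.std,
        }


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with positive class = 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have identical shape")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(
    c: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricsReport:
    """ACC/SN/PE/MCC from counts, plus rank-based AUC when scores given.

    Zero-denominator conventions: SN, PE and MCC are 0 when undefined;
    AUC is 0.5 when either class is absent.
    """
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    sn = _safe_div(tp, tp + fn)
    pe = _safe_div(tp, tp + fp)
    denom = np.sqrt((tp + fp) * (tn + fp) * (tn + fn) * (fn + tp))
    mcc = _safe_div(tn * tp - fn * fp, denom)
    if scores is not None and y_true is not None:
        auc, _ = roc_auc(scores, y_true)
    else:
        auc = 0.5
    return MetricsReport(acc=acc, sn=sn, pe=pe, mcc=mcc, auc=auc, counts=c)


def roc_auc(
    scores: np.ndarray, y_true: np.ndarray
) -> tuple[float, np.ndarray]:
    """Rank-based AUC plus ROC curve points.

    AUC is the Mann-Whitney statistic: the fraction of (positive,
    negative) pairs with score_pos > score_neg, ties counted 1/2 —
    invariant under any strictly monotone transform of the scores.  Curve
    points are (FPR, TPR) swept across all score thresholds, from (0, 0)
    to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5, np.array([[0.0, 0.0], [1.0, 1.0]])
    ranks = rankdata(scores)  # average ranks handle ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = (y_true[order] == 1).astype(float)
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(1.0 - sorted_pos)
    # Keep the last index of each tied-score block.
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
    fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
    return float(auc), np.stack([fpr, tpr], axis=1)


def kfold_split(
    n: int,
    k: int = 5,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Seeded disjoint index folds of sizes differing by at most one.

    With labels given, each class is dealt round-robin after a seeded
    shuffle so class proportions are preserved per fold.
    """
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratify_labels is None:
        order = rng.permutation(n)
        for i, idx in enumerate(order):
            folds[i % k].append(int(idx))
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape[0] != n:
            raise ValueError("stratify_labels length must equal n")
        offset = 0
        for value in np.unique(labels):
            members = rng.permutation(np.flatnonzero(labels == value))
            for i, idx in enumerate(members):
                folds[(i + offset) % k].append(int(idx))
            offset += len(members)  # stagger so remainders spread over folds
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate_features(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: "object | None" = None,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> CVReport:
    """k-fold cross-validation of the full pipeline on a feature matrix.

    Within each fold the SDAE (if enabled) and the ferns model are trained
    only on the k-1 training folds; feature ranges, encodings and all
    parameters are recomputed per fold.
    """
    from .model import PPIModel, PipelineConfig

    if pipeline is None:
        pipeline = PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = kfold_split(len(y), k=k, seed=seed,
                        stratify_labels=y if stratify else None)
    reports = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        y_test = y[test_idx]
        if len(np.unique(y_test)) < 2 or len(np.unique(y[train_mask])) < 2:
            raise ValueError(f"fold {i} contains a single class")
        results = PPIModel(X[train_mask], y[train_mask], config=pipeline).fit()
        scores = results.predict_proba(X[test_idx])[:, 1]
        y_pred = (scores > 0.5).astype(int)
        reports.append(compute_metrics(confusion(y_test, y_pred), scores, y_test))
    return CVReport(per_fold=reports)


def cross_validate(
    pairs: PairTable,
    pssm_lookup: Mapping[str, PSSMatrix],
    pipeline: "object | None" = None,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> CVReport:
    """Featurize a pair table and cross-validate the full pipeline.

    The per-protein cross-product transform is stateless (no statistics
    fitted across proteins), so features can be computed once up front
    without leaking fold information; everything fitted (SDAE, ferns,
    feature ranges) is retrained inside each fold.
    """
    from .featurize import feature_matrix, featurize_dataset
    from .model import PipelineConfig

    if pipeline is None:
        pipeline = PipelineConfig()
    vectors = featurize_dataset(pairs, pssm_lookup, pipeline.featurization)
    X, y, _ = feature_matrix(vectors)
    return cross_validate_features(X, y, pipeline, k=k, seed=seed, stratify=stratify)
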