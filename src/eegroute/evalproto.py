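"""Subject-independent evaluation: grouped 5-fold CV, AdamW training with
early stopping, and the confusion-matrix / ROC metric suite.

All splitting is by subject: every epoch of a subject falls entirely in
train, validation or test of a given fold, and each subject is tested
exactly once across the five folds.  Normalization statistics are fitted on
the training fold only (see :mod:`eegroute.tensorize`), and early stopping
consults only the inner validation subjects — the test fold is never touched
before the final evaluation.

Metric conventions: MDD is the positive class for precision/recall/F1;
HC is the negative class for specificity and FPR.  Metrics are epoch-level
(the classification unit is the 2-s epoch, so the confusion matrix counts
epochs, not subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.model_selection import GroupKFold

from .model import BiLSTMRoutingClassifier, ModelConfig
from .nn import AdamW, margin_loss_forward
from .tensorize import EpochSet, apply_normalizer, fit_normalizer

__all__ = [
    "FoldSplit", "TrainSpec", "MetricsReport", "TrainHistory",
    "group_kfold_splits", "train_fold", "confusion_metrics", "roc_auc",
    "cross_validate", "CVResult",
]


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subjects: frozenset[str]

    def __post_init__(self) -> None:
        if (self.train_subjects & self.val_subjects
                or self.train_subjects & self.test_subjects
                or self.val_subjects & self.test_subjects):
            raise ValueError("fold subject sets must be pairwise disjoint")


@dataclass(frozen=True)
class TrainSpec:
    lr: float = 2e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    weight_decay: float = 1e-2
    monitor: str = "val_loss"  # or "val_acc"
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be > 0 and batch_size >= 1")
        if self.monitor not in ("val_loss", "val_acc"):
            raise ValueError("monitor must be val_loss or val_acc")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class MetricsReport:
    """Epoch-level confusion matrix and derived rates (percentages).

    Rates with a zero denominator are reported as None (undefined), never 0.
    """

    confusion: np.ndarray  # 2x2, rows true [HC, MDD], cols predicted
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    specificity: float | None
    ppv: float | None
    sensitivity: float | None
    fpr: float | None
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None


def _pct(num: float, den: float) -> float | None:
    if den == 0:
        return None
    return round(100.0 * num / den, 2)


def confusion_metrics(confusion: np.ndarray) -> MetricsReport:
    """Derive the clinical rate suite from a 2x2 confusion matrix.

    Layout: rows are true [HC, MDD], columns predicted [HC, MDD], so
    TN = [0,0], FP = [0,1], FN = [1,0], TP = [1,1].
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2) or np.any(confusion < 0):
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    tn, fp = float(confusion[0, 0]), float(confusion[0, 1])
    fn, tp = float(confusion[1, 0]), float(confusion[1, 1])
    total = tn + fp + fn + tp
    precision = _pct(tp, tp + fp)
    recall = _pct(tp, tp + fn)
    f1 = _pct(2 * tp, 2 * tp + fp + fn)  # harmonic mean, from counts
    return MetricsReport(
        confusion=confusion,
        accuracy=_pct(tn + tp, total),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_pct(tn, tn + fp),
        ppv=precision,
        sensitivity=recall,
        fpr=_pct(fp, tn + fp),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """Trapezoidal AUC over all thresholds plus the ROC points.

    Equivalent to the Mann-Whitney probability of ranking a random MDD epoch
    above a random HC epoch, with ties counted as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(sk_auc(fpr, tpr)), list(zip(fpr.tolist(), tpr.tolist()))


def group_kfold_splits(subject_ids, k: int = 5, val_fraction: float = 0.2,
                       seed: int = 0) -> list[FoldSplit]:
    """Grouped k-fold over subjects with an inner grouped validation split.

    Subjects are shuffled with the seed, assigned to k test folds with
    GroupKFold, and ``val_fraction`` of each fold's training *subjects* are
    carved out for early stopping (grouped, preserving subject independence).
    """
    subjects = np.array(sorted(set(map(str, subject_ids))))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    subjects = subjects[rng.permutation(len(subjects))]
    splitter = GroupKFold(n_splits=k)
    splits = []
    for fold_id, (train_idx, test_idx) in enumerate(
            splitter.split(subjects, groups=subjects)):
        train_pool = subjects[train_idx]
        test = frozenset(subjects[test_idx])
        n_val = max(1, int(round(val_fraction * len(train_pool))))
        val_pick = rng.choice(len(train_pool), size=n_val, replace=False)
        val = frozenset(train_pool[val_pick])
        train = frozenset(train_pool) - val
        splits.append(FoldSplit(fold_id, train, val, test))
    return splits


def _subset(epochs: EpochSet, subjects: frozenset[str]) -> EpochSet:
    mask = np.isin(epochs.subject_ids, list(subjects))
    return epochs.select(mask)


def _evaluate(model: BiLSTMRoutingClassifier, data: EpochSet):
    out = model.predict(data.as_model_input())
    loss, _ = margin_loss_forward(
        out.class_norms, data.labels, model.config.m_plus,
        model.config.m_minus, model.config.lam)
    acc = float(np.mean(out.prediction == data.labels))
    return loss, acc, out


def train_fold(train: EpochSet, val: EpochSet, config: ModelConfig,
               spec: TrainSpec) -> tuple[BiLSTMRoutingClassifier, TrainHistory]:
    """Minimize the margin loss with AdamW; early-stop on validation loss.

    Stops once validation loss has failed to improve for ``patience``
    consecutive epochs and restores the best-validation weights.
    Deterministic given the seeds in config and spec.
    """
    if train.n_epochs == 0:
        raise ValueError("empty training set")
    if train.units != "normalized" or val.units != "normalized":
        raise ValueError("train_fold expects normalized epochs")
    model = BiLSTMRoutingClassifier(config)
    opt = AdamW(model.params, lr=spec.lr, weight_decay=spec.weight_decay)
    rng = np.random.default_rng(spec.seed)
    x = train.as_model_input().astype(np.dtype(config.dtype))  # cast once
    y = train.labels
    history = TrainHistory()
    best_score = np.inf
    best_params = model.copy_params()
    since_best = 0
    for ep in range(spec.max_epochs):
        order = rng.permutation(len(y))
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, len(y), spec.batch_size):
            idx = order[start:start + spec.batch_size]
            loss, grads, out = model.loss_and_grads(x[idx], y[idx])
            opt.step(grads)
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum(out.prediction == y[idx]))
        history.train_loss.append(ep_loss / len(y))
        history.train_acc.append(ep_correct / len(y))
        val_loss, val_acc, _ = _evaluate(model, val)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        # early stopping consults only the inner validation split
        score = val_loss if spec.monitor == "val_loss" else -val_acc
        if score < best_score:
            best_score = score
            best_params = model.copy_params()
            history.best_epoch = ep
            since_best = 0
        else:
            since_best += 1
            if since_best > spec.patience:
                break
    if spec.restore_best:
        model.set_params(best_params)
    else:
        history.best_epoch = len(history.train_loss) - 1
    return model, history


@dataclass
class CVResult:
    splits: list[FoldSplit]
    fold_reports: list[MetricsReport]
    pooled_report: MetricsReport
    histories: list[TrainHistory]
    test_scores: np.ndarray  # pooled per-epoch MDD confidence
    test_labels: np.ndarray
    test_predictions: np.ndarray


def cross_validate(epochs: EpochSet, config: ModelConfig, spec: TrainSpec,
                   k: int = 5, val_fraction: float = 0.2,
                   split_seed: int = 0) -> CVResult:
    """Full subject-independent k-fold protocol on physical-unit epochs.

    Per fold: fit NormStats on the training subjects' epochs, normalize
    train/val/test with those stats, train with early stopping, evaluate on
    the held-out subjects.  Reports per-fold metrics, the pooled confusion
    matrix (sum over folds) and a pooled ROC over all test epochs.
    """
    if epochs.units != "uV":
        raise ValueError("cross_validate expects physical-unit epochs; "
                         "normalization is fold-wise and happens inside")
    splits = group_kfold_splits(epochs.subject_ids, k=k,
                                val_fraction=val_fraction, seed=split_seed)
    fold_reports: list[MetricsReport] = []
    histories: list[TrainHistory] = []
    all_scores, all_labels, all_preds = [], [], []
    pooled_conf = np.zeros((2, 2), dtype=int)
    for split in splits:
        tr = _subset(epochs, split.train_subjects)
        va = _subset(epochs, split.val_subjects)
        te = _subset(epochs, split.test_subjects)
        stats = fit_normalizer(tr, fold_id=split.fold_id)
        tr_n = apply_normalizer(tr, stats)
        va_n = apply_normalizer(va, stats)
        te_n = apply_normalizer(te, stats)
        model, history = train_fold(tr_n, va_n, config, spec)
        histories.append(history)
        out = model.predict(te_n.as_model_input())
        conf = np.zeros((2, 2), dtype=int)
        for true, pred in zip(te.labels, out.prediction):
            conf[true, pred] += 1
        pooled_conf += conf
        scores = out.class_norms[:, 1]  # MDD confidence
        report = confusion_metrics(conf)
        if len(np.unique(te.labels)) == 2:
            report.auc, report.roc_points = roc_auc(scores, te.labels)
        fold_reports.append(report)
        all_scores.append(scores)
        all_labels.append(te.labels)
        all_preds.append(out.prediction)
    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    preds = np.concatenate(all_preds)
    pooled = confusion_metrics(pooled_conf)
    pooled.auc, pooled.roc_points = roc_auc(scores, labels)
    return CVResult(splits=splits, fold_reports=fold_reports,
                    pooled_report=pooled, histories=histories,
                    test_scores=scores, test_labels=labels,
                    test_predictions=preds)
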