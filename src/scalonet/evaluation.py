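"""Subject-wise cross-validation and the classification metrics suite.

Folds are assigned per subject, never per tile: every tile of a subject lives
in exactly one fold, so no individual contributes images to both the training
and validation side of any fold.  Within each class subjects are shuffled
(seeded) and dealt round-robin, which keeps folds approximately class
balanced even with only 15-16 subjects per class.

Metrics: accuracy = trace/total; binary sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) with the disease class (label 1 of the binary
problem) as positive; zero-denominator cases are reported as NaN, never as
0.  Multi-class problems get per-class one-vs-rest sensitivity/specificity
plus macro averages.  Agreement beyond chance is measured with the
quadratic weighted kappa

    K = 1 - sum_ij w(i,j) c(i,j) / sum_ij w(i,j) p(i,j),

where c is the normalized confusion matrix, p the outer product of its two
marginal distributions and w(i,j) = (i-j)^2 (a signed linear weight variant
is available behind a flag but is not the default, since it is
sign-indefinite and contradicts the statistic's name).  ROC curves and AUC
use the standard threshold sweep; the AUC equals the rank statistic with
ties counted half.

The cross-validation driver reports both the mean over folds of each metric
and the metrics of the pooled confusion matrix, labeling each — the two do
not coincide in general.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CnnSpec, TrainConfig, build_cnn, decide, predict_proba
from .model import train as train_model
from .timefreq import TileSet

__all__ = [
    "EXPERIMENTS",
    "FoldSplit",
    "MetricsReport",
    "RocResult",
    "CrossValResult",
    "make_subject_folds",
    "confusion_matrix",
    "classification_metrics",
    "quadratic_weighted_kappa",
    "roc_and_auc",
    "cross_validate",
    "audit_no_leakage",
]

#: Named experiments: classes kept (original labels) and the remapping to
#: the contiguous labels the classifier is trained on.
EXPERIMENTS: dict[str, dict[int, int]] = {
    "hc-vs-off": {0: 0, 1: 1},
    "off-vs-on": {1: 0, 2: 1},
    "three-class": {0: 0, 1: 1, 2: 2},
}


@dataclass(frozen=True)
class FoldSplit:
    """Partition of subjects into k folds."""

    k: int
    assignment: Mapping[str, int]
    seed: int = 0

    def subjects_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


@dataclass
class MetricsReport:
    """Accuracy/sensitivity/specificity (plus kappa/AUC when computed)."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray = field(repr=False)
    kappa: float = float("nan")
    auc: float = float("nan")
    per_class: dict | None = None

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
        }
        if self.per_class is not None:
            out["per_class"] = self.per_class
        return out


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    defined: bool = True


def make_subject_folds(
    subject_labels: Mapping[str, int], k: int, seed: int = 0
) -> FoldSplit:
    """Deal subjects into k folds, round-robin within each class.

    ``subject_labels`` maps subject_id -> class label.  Deterministic for a
    fixed seed.  Raises if ``k`` exceeds the number of subjects.
    """
    subjects = list(subject_labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(subjects):
        raise ValueError(
            f"k={k} folds but only {len(subjects)} subjects are available"
        )
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for label in sorted(set(subject_labels.values())):
        members = sorted(s for s in subjects if subject_labels[s] == label)
        rng.shuffle(members)
        for i, s in enumerate(members):
            assignment[s] = (i + offset) % k
        offset += len(members)  # rotate so small classes spread evenly
    return FoldSplit(k=k, assignment=assignment, seed=seed)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts[i, j] = #(true class i, predicted class j)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes
        or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return counts


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(confusion: np.ndarray) -> MetricsReport:
    """Accuracy, sensitivity and specificity from a confusion matrix.

    Binary matrices use the convention rows = truth, columns = prediction,
    class 1 = positive (the disease class): TN = [0,0], FP = [0,1],
    FN = [1,0], TP = [1,1].  Larger matrices report per-class one-vs-rest
    values and their macro averages.
    """
    confusion = np.asarray(confusion, dtype=np.int64)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion must be a square matrix")
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = float(np.trace(confusion)) / total
    L = confusion.shape[0]
    if L == 2:
        tn, fp = int(confusion[0, 0]), int(confusion[0, 1])
        fn, tp = int(confusion[1, 0]), int(confusion[1, 1])
        return MetricsReport(
            accuracy=accuracy,
            sensitivity=_safe_ratio(tp, tp + fn),
            specificity=_safe_ratio(tn, tn + fp),
            confusion=confusion,
        )
    per_class = {}
    for c in range(L):
        tp = int(confusion[c, c])
        fn = int(confusion[c].sum() - tp)
        fp = int(confusion[:, c].sum() - tp)
        tn = total - tp - fn - fp
        per_class[c] = {
            "sensitivity": _safe_ratio(tp, tp + fn),
            "specificity": _safe_ratio(tn, tn + fp),
        }
    sens = [v["sensitivity"] for v in per_class.values()]
    spec = [v["specificity"] for v in per_class.values()]
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        confusion=confusion,
        per_class=per_class,
    )


def quadratic_weighted_kappa(
    confusion: np.ndarray, weights: str = "quadratic"
) -> float:
    """Weighted kappa K = 1 - sum(w*c)/sum(w*p).

    ``c`` is the confusion matrix normalized to a joint distribution, ``p``
    the outer product of its row and column marginals, and
    w(i,j) = (i-j)^2 by default.  ``weights="linear_signed"`` evaluates the
    sign-indefinite w(i,j) = (i-j) variant.  Returns NaN when the chance
    term sum(w*p) is zero (all mass on one diagonal cell).
    """
    confusion = np.asarray(confusion, dtype=np.float64)
    total = confusion.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    L = confusion.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    if weights == "quadratic":
        w = (i - j) ** 2
    elif weights == "linear_signed":
        w = i - j
    else:
        raise ValueError("weights must be 'quadratic' or 'linear_signed'")
    c = confusion / total
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    p = np.outer(row, col)
    denom = float((w * p).sum())
    if denom == 0:
        return float("nan")
    return 1.0 - float((w * c).sum()) / denom


def roc_and_auc(scores, labels, positive_class: int = 1) -> RocResult:
    """ROC by threshold sweep and AUC by the trapezoidal rule.

    ``scores`` are positive-class probabilities (or any monotone score).
    The AUC equals the Mann-Whitney rank statistic: the probability that a
    random positive outscores a random negative, ties counted half.
    Returns an undefined result (NaN AUC) when only one class is present.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=np.float64)
    y = (np.asarray(labels) == positive_class).astype(np.int64)
    if y.min() == y.max():
        return RocResult(
            np.array([]), np.array([]), np.array([]), float("nan"),
            defined=False,
        )
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr, tpr, thresholds, auc)


@dataclass
class CrossValResult:
    """Per-fold and aggregate views of one cross-validated experiment."""

    experiment: str
    folds: FoldSplit
    fold_metrics: list[MetricsReport]
    pooled: MetricsReport
    mean_of_folds: dict[str, float]
    predictions: pd.DataFrame = field(repr=False)
    histories: list[pd.DataFrame] = field(repr=False, default_factory=list)

    def summary(self) -> dict:
        return {
            "experiment": self.experiment,
            "k": self.folds.k,
            "mean_of_folds": self.mean_of_folds,
            "pooled": self.pooled.as_dict(),
            "per_fold": [m.as_dict() for m in self.fold_metrics],
        }


def _experiment_tiles(tiles: TileSet, experiment: str):
    if experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; choose from {list(EXPERIMENTS)}"
        )
    mapping = EXPERIMENTS[experiment]
    labels = tiles.labels
    mask = np.isin(labels, list(mapping))
    present = set(labels[mask].tolist())
    missing = set(mapping) - present
    if missing:
        raise ValueError(
            f"experiment {experiment!r} needs class(es) {sorted(missing)} "
            "which are absent from the tiles"
        )
    images = tiles.images[mask]
    meta = tiles.meta.loc[mask].reset_index(drop=True)
    mapped = meta["class_label"].map(mapping).to_numpy(dtype=np.int64)
    return images, meta, mapped, len(mapping)


def cross_validate(
    tiles: TileSet,
    experiment: str,
    k: int = 4,
    cnn_spec: CnnSpec | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    threshold: float | None = 0.5,
    folds: FoldSplit | None = None,
) -> CrossValResult:
    """Run one experiment under subject-wise k-fold cross-validation.

    For every fold a fresh model is initialized (seeded per fold), trained on
    the training subjects' tiles and evaluated on the validation subjects'
    tiles.  Reports per-fold metrics, the pooled confusion matrix/ROC over
    all validation predictions, and the cross-fold mean of each metric.
    """
    if train_config is None:
        train_config = TrainConfig()
    images, meta, labels, n_classes = _experiment_tiles(tiles, experiment)
    subject_labels = (
        meta.assign(label=labels)
        .groupby("subject_id")["label"]
        .first()
        .to_dict()
    )
    if folds is None:
        folds = make_subject_folds(subject_labels, k, seed)
    subjects = meta["subject_id"].to_numpy()
    fold_of_tile = np.array([folds.assignment[s] for s in subjects])
    fold_metrics: list[MetricsReport] = []
    histories = []
    pred_rows = []
    for fold in range(folds.k):
        val_mask = fold_of_tile == fold
        train_mask = ~val_mask
        if not val_mask.any() or not train_mask.any():
            raise ValueError(f"fold {fold} has an empty train or validation side")
        net = build_cnn(cnn_spec, n_classes=n_classes,
                        seed=seed * 1000 + fold)
        fold_cfg = TrainConfig(**{**train_config.__dict__,
                                  "seed": train_config.seed * 1000 + fold})
        history = train_model(net, images[train_mask], labels[train_mask],
                              fold_cfg)
        histories.append(history)
        probs = predict_proba(net, images[val_mask])
        preds = decide(probs, threshold if n_classes == 2 else None)
        conf = confusion_matrix(labels[val_mask], preds, n_classes)
        report = classification_metrics(conf)
        report.kappa = quadratic_weighted_kappa(conf)
        if n_classes == 2:
            roc = roc_and_auc(probs[:, 1], labels[val_mask])
            report.auc = roc.auc
        else:
            aucs = [roc_and_auc(probs[:, c], labels[val_mask],
                                positive_class=c).auc for c in range(n_classes)]
            report.auc = float(np.mean(aucs))
        fold_metrics.append(report)
        vmeta = meta.loc[val_mask]
        pred_rows.append(
            pd.DataFrame(
                {
                    "subject_id": vmeta["subject_id"].to_numpy(),
                    "channel": vmeta["channel"].to_numpy(),
                    "tile_index": vmeta["tile_index"].to_numpy(),
                    "fold": fold,
                    "true": labels[val_mask],
                    "predicted": preds,
                    "score": probs[:, 1] if n_classes == 2
                    else probs.max(axis=1),
                }
            )
        )
    predictions = pd.concat(pred_rows, ignore_index=True)
    pooled_conf = sum(m.confusion for m in fold_metrics)
    pooled = classification_metrics(pooled_conf)
    pooled.kappa = quadratic_weighted_kappa(pooled_conf)
    if n_classes == 2:
        pooled.auc = roc_and_auc(
            predictions["score"].to_numpy(), predictions["true"].to_numpy()
        ).auc
    else:
        pooled.auc = float(np.nanmean([m.auc for m in fold_metrics]))
    mean_of_folds = {
        key: float(np.mean([getattr(m, key) for m in fold_metrics]))
        for key in ("accuracy", "sensitivity", "specificity", "kappa", "auc")
    }
    return CrossValResult(
        experiment=experiment,
        folds=folds,
        fold_metrics=fold_metrics,
        pooled=pooled,
        mean_of_folds=mean_of_folds,
        predictions=predictions,
        histories=histories,
    )


def audit_no_leakage(result: CrossValResult) -> bool:
    """Re-derive fold membership from the prediction log and assert that no
    subject was validated in more than one fold."""
    by_subject = result.predictions.groupby("subject_id")["fold"].nunique()
    if (by_subject > 1).any():
        leaky = by_subject[by_subject > 1].index.tolist()
        raise AssertionError(f"subject(s) validated in multiple folds: {leaky}")
    return True
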