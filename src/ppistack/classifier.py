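"""Meta-level classification: unit-variance scaling, AdaBoost, CV report.

The feature matrix (rows = candidate pairs, columns = the six evidence
scores) is scaled to unit variance column-wise — scale only, no mean
centering, sample standard deviation with the n-1 denominator — and fed to
an AdaBoost ensemble of depth-1 decision trees (the canonical stump
configuration, 100 rounds). Training reports stratified 10-fold
cross-validation metrics from pooled out-of-fold predictions and refits
the final model on all rows. Everything is reproducible bit-identically
from the experiment seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, FeatureVector

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
DECISION_THRESHOLD = 0.5


@dataclass
class FeatureMatrix:
    """Ordered pair ids x six named feature columns, optional 0/1 labels."""

    pairs: list[tuple[str, str]]
    values: pd.DataFrame  # columns FEATURE_COLUMNS, no missing values
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != tuple(FEATURE_COLUMNS):
            raise ValueError(
                f"feature columns must be {FEATURE_COLUMNS}, got {tuple(self.values.columns)}"
            )
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.pairs):
                raise ValueError("labels not aligned to rows")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[FeatureVector], labels: Optional[Sequence[int]] = None
    ) -> "FeatureMatrix":
        values = pd.DataFrame(
            [v.scores for v in vectors], columns=list(FEATURE_COLUMNS), dtype=float
        )
        return cls(
            pairs=[v.pair for v in vectors],
            values=values,
            labels=None if labels is None else np.asarray(labels, dtype=int),
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "id_a", [p[0] for p in self.pairs])
        out.insert(1, "id_b", [p[1] for p in self.pairs])
        if self.labels is not None:
            out["label"] = self.labels
        out.to_csv(path, index=False, float_format="%.10g")


def normalize_unit_variance(
    matrix: np.ndarray, stats: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each column by its sample standard deviation (no centering).

    Zero-variance columns pass through unchanged with a warning (their
    scale statistic is recorded as 1.0). When ``stats`` is given (test
    time) the stored statistics are reused, never refit.
    """
    matrix = np.asarray(matrix, dtype=float)
    if stats is None:
        stats = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.ones(matrix.shape[1])
        zero = stats == 0.0
        if zero.any():
            cols = [FEATURE_COLUMNS[i] for i in np.flatnonzero(zero) if i < len(FEATURE_COLUMNS)]
            warnings.warn(f"zero-variance columns passed through unscaled: {cols or np.flatnonzero(zero).tolist()}")
            stats = np.where(zero, 1.0, stats)
    return matrix / stats, np.asarray(stats, dtype=float)


@dataclass
class TrainedModel:
    """Scale statistics + fitted boosted ensemble + column order + seed."""

    scale: np.ndarray
    ensemble: AdaBoostClassifier
    columns: tuple[str, ...]
    seed: int
    n_estimators: int = 100
    format_version: int = MODEL_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": self.format_version,
                "scale": self.scale,
                "ensemble": self.ensemble,
                "columns": self.columns,
                "seed": self.seed,
                "n_estimators": self.n_estimators,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {blob.get('format_version')!r}")
        return cls(
            scale=blob["scale"],
            ensemble=blob["ensemble"],
            columns=tuple(blob["columns"]),
            seed=blob["seed"],
            n_estimators=blob["n_estimators"],
        )


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    roc_points: list[tuple[float, float]]
    auc: float
    per_fold: list[dict] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion_matrix": self.confusion.tolist(),
            "roc_points": [list(p) for p in self.roc_points],
            "auc": self.auc,
            "per_fold": self.per_fold,
        }


def _confusion(calls: np.ndarray, truth: np.ndarray) -> np.ndarray:
    tp = int(np.sum((calls == 1) & (truth == 1)))
    tn = int(np.sum((calls == 0) & (truth == 0)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    return np.array([[tn, fp], [fn, tp]])


def evaluate(
    calls: Sequence[int], probabilities: Sequence[float], truth: Sequence[int]
) -> EvaluationReport:
    """Metrics report from hard calls, scores and ground truth.

    The ROC is built by sweeping the probability threshold; AUC by the
    trapezoid rule. Undefined precision/recall/F1 (empty denominators)
    report 0.
    """
    calls = np.asarray(calls, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if not (len(calls) == len(probabilities) == len(truth)):
        raise ValueError(
            f"length mismatch: calls={len(calls)}, probabilities={len(probabilities)}, truth={len(truth)}"
        )
    cm = _confusion(calls, truth)
    (tn, fp), (fn, tp) = cm
    n = cm.sum()
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    if len(np.unique(truth)) == 2:
        fpr, tpr, _ = roc_curve(truth, probabilities)
        auc = float(np.trapezoid(tpr, fpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    else:  # degenerate: single-class truth has no ROC
        roc_points = [(0.0, 0.0), (1.0, 1.0)]
        auc = 0.5
    report = EvaluationReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        confusion=cm,
        roc_points=roc_points,
        auc=auc,
    )
    _assert_self_consistent(report, len(truth))
    return report


def _assert_self_consistent(report: EvaluationReport, n: int) -> None:
    cm = report.confusion
    assert int(cm.sum()) == n, "confusion counts must sum to n"
    (tn, fp), (fn, tp) = cm
    assert abs(report.accuracy - (tp + tn) / max(n, 1)) < 1e-12
    if report.precision + report.recall > 0:
        expected_f1 = 2 * report.precision * report.recall / (report.precision + report.recall)
        assert abs(report.f1 - expected_f1) < 1e-12


def _new_ensemble(seed: int, n_estimators: int) -> AdaBoostClassifier:
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
        n_estimators=n_estimators,
        random_state=seed,
    )


def train(
    matrix: FeatureMatrix, seed: int, n_estimators: int = 100, n_folds: int = 10
) -> tuple[TrainedModel, EvaluationReport]:
    """Fit the boosted meta-classifier with a stratified CV report.

    Per-fold metrics are recorded and the headline report pools the
    out-of-fold predictions (so its confusion matrix sums to n). The final
    model is refit on all rows after scaling.
    """
    if matrix.labels is None:
        raise ValueError("training requires labels")
    y = matrix.labels
    if len(y) < 20:
        raise ValueError(f"training requires at least 20 rows, got {len(y)}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training requires both classes, got only {classes.tolist()}")
    x_raw = matrix.values.to_numpy(dtype=float)
    x, scale = normalize_unit_variance(x_raw)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled_calls = np.empty(len(y), dtype=int)
    pooled_probs = np.empty(len(y), dtype=float)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(cv.split(x, y)):
        clf = _new_ensemble(seed, n_estimators)
        clf.fit(x[train_idx], y[train_idx])
        probs = clf.predict_proba(x[test_idx])[:, 1]
        calls = (probs >= DECISION_THRESHOLD).astype(int)
        pooled_probs[test_idx] = probs
        pooled_calls[test_idx] = calls
        fold_report = evaluate(calls, probs, y[test_idx])
        per_fold.append(
            {
                "fold": fold,
                "accuracy": fold_report.accuracy,
                "precision": fold_report.precision,
                "recall": fold_report.recall,
                "f1": fold_report.f1,
            }
        )
    report = evaluate(pooled_calls, pooled_probs, y)
    report.per_fold = per_fold

    final = _new_ensemble(seed, n_estimators)
    final.fit(x, y)
    model = TrainedModel(
        scale=scale,
        ensemble=final,
        columns=tuple(FEATURE_COLUMNS),
        seed=seed,
        n_estimators=n_estimators,
    )
    logger.info(
        "trained AdaBoost (%d stumps) on %d rows; CV accuracy %.4f, confusion %s",
        n_estimators,
        len(y),
        report.accuracy,
        report.confusion.tolist(),
    )
    return model, report


def predict(
    model: TrainedModel, matrix: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Probabilities, 0/1 calls and the positively predicted pairs.

    The matrix is scaled with the model's stored statistics (never refit).
    The positive list preserves input row order.
    """
    if tuple(matrix.values.columns) != model.columns:
        raise ValueError(
            f"feature columns {tuple(matrix.values.columns)} do not match "
            f"the model's recorded order {model.columns}"
        )
    if len(matrix) == 0:
        return np.empty(0), np.empty(0, dtype=int), []
    x, _ = normalize_unit_variance(matrix.values.to_numpy(dtype=float), stats=model.scale)
    probs = model.ensemble.predict_proba(x)[:, 1]
    calls = (probs >= DECISION_THRESHOLD).astype(int)
    positives = [pair for pair, call in zip(matrix.pairs, calls) if call == 1]
    return probs, calls, positives
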