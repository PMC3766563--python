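"""Cross-validation protocols and performance metrics.

Sensitivity, specificity and accuracy come straight from the confusion
counts:

    Sn = TP / (TP + FN),  Sp = TN / (TN + FP),  Acc = (TP + TN) / N.

The ROC curve is traced by sweeping the decision threshold over the
distinct held-out scores; its trapezoidal area (auROC) equals the
pairwise rank statistic (#[pos > neg] + 0.5 #[pos = neg]) / (n_pos *
n_neg), with tied scores earning half credit.

The jackknife (leave-one-out) protocol refits the model n times, each
time scoring the single held-out protein, and pools the n held-out
predictions into one confusion matrix -- the most stringent deterministic
estimate available for a dataset of this size. Stratified k-fold is the
cheaper seeded alternative used during feature selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._utils import stratified_fold_indices
from .features import FeatureMatrix
from .naive_bayes import GaussianNaiveBayes, NaiveBayesResults, tune_theta

#: class-call strings used in prediction tables
POSITIVE_CALL = "Antioxidant"
NEGATIVE_CALL = "Nonantioxidant"

Trainer = Callable[[FeatureMatrix, np.ndarray], NaiveBayesResults]


class EvaluationError(ValueError):
    """Raised on protocols that cannot run on the given data."""


def _default_trainer(fm: FeatureMatrix, labels: np.ndarray):
    return GaussianNaiveBayes(fm, labels).fit()


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) from binary predictions and truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return tp, tn, fp, fn


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Confusion counts plus Sn/Sp/Acc.

    A rate whose denominator class is absent is reported as ``None``
    (explicitly undefined), never as silent NaN.
    """
    tp, tn, fp, fn = confusion_counts(pred, truth)
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty prediction set")
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "sn": tp / (tp + fn) if (tp + fn) else None,
        "sp": tn / (tn + fp) if (tn + fp) else None,
        "acc": (tp + tn) / n,
    }


def roc_points(scores: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """ROC polyline (FPR, TPR) from sweeping the threshold over all scores.

    Starts at (0, 0), ends at (1, 1); tied scores are grouped into one
    step so ties trace a diagonal segment.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both classes present")
    if not np.isfinite(scores).all():
        raise EvaluationError("ROC needs finite scores")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = truth[order]
    # group tied scores: indices where a threshold step ends
    distinct = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y == 1)[ends] / n_pos
    fps = np.cumsum(y == 0)[ends] / n_neg
    return np.vstack([[0.0, 0.0], np.column_stack([fps, tps])])


def roc_auroc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """(ROC points, trapezoidal auROC)."""
    pts = roc_points(scores, truth)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


@dataclass
class EvalReport:
    """Pooled evaluation of one protocol run."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float | None
    sp: float | None
    acc: float
    roc_points: np.ndarray | None
    auroc: float | None
    per_sample: pd.DataFrame
    protocol: str
    theta_used: float | str
    per_fold_thetas: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    def summary(self) -> str:
        def pct(v):
            return "undefined" if v is None else f"{100 * v:.2f}%"

        lines = [
            f"protocol:  {self.protocol}   (n = {self.n}, theta = "
            f"{self.theta_used})",
            f"confusion: TP={self.tp} FN={self.fn} TN={self.tn} FP={self.fp}",
            f"Sn = {pct(self.sn)}   Sp = {pct(self.sp)}   "
            f"Acc = {pct(self.acc)}",
        ]
        if self.auroc is not None:
            lines.append(f"auROC = {self.auroc:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "theta_used": self.theta_used,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "auroc": self.auroc,
            "roc_points": None
            if self.roc_points is None
            else self.roc_points.tolist(),
            "per_sample": self.per_sample.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            path, sep="\t", index=False
        )

    def plot_roc(self, ax=None):
        """Plot the ROC curve (matplotlib Axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1], drawstyle=None)
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("false positive rate (1 - Sp)")
        ax.set_ylabel("true positive rate (Sn)")
        ax.set_title(f"{self.protocol}: auROC = {self.auroc:.3f}")
        return ax


def _pooled_report(
    ids,
    truth: np.ndarray,
    scores: np.ndarray,
    pred: np.ndarray,
    protocol: str,
    theta_used,
    per_fold_thetas: list[float] | None = None,
) -> EvalReport:
    metrics = confusion_metrics(pred, truth)
    both = (truth == 1).any() and (truth == 0).any()
    if both:
        pts, auc = roc_auroc(scores, truth)
    else:
        pts, auc = None, None
    per_sample = pd.DataFrame(
        {
            "id": list(ids),
            "label": truth.astype(int),
            "score": scores,
            "pred": pred.astype(int),
            "call": [POSITIVE_CALL if p else NEGATIVE_CALL for p in pred],
        }
    )
    return EvalReport(
        tp=metrics["tp"],
        tn=metrics["tn"],
        fp=metrics["fp"],
        fn=metrics["fn"],
        sn=metrics["sn"],
        sp=metrics["sp"],
        acc=metrics["acc"],
        roc_points=pts,
        auroc=auc,
        per_sample=per_sample,
        protocol=protocol,
        theta_used=theta_used,
        per_fold_thetas=per_fold_thetas or [],
    )


def _resolve_fold(
    fm: FeatureMatrix,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    trainer: Trainer,
    theta,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit on train, score test; returns (scores, pred, theta used)."""
    y_train = labels[train_idx]
    if len(np.unique(y_train)) < 2:
        raise EvaluationError("a training fold lost one class entirely")
    results = trainer(fm.rows(train_idx), y_train)
    scores = results.log_odds(fm.rows(test_idx))
    if theta == "tune":
        train_scores = results.log_odds(fm.rows(train_idx))
        th = tune_theta(train_scores, y_train)
    else:
        th = float(theta)
    return scores, (scores >= th).astype(int), th


def jackknife(
    fm: FeatureMatrix,
    labels: np.ndarray,
    trainer: Trainer | None = None,
    theta: float | str = 0.0,
) -> EvalReport:
    """Leave-one-out evaluation: n fits, each scoring its held-out sample.

    ``theta`` is either a fixed threshold applied to every held-out score
    or ``"tune"`` to re-tune the threshold on each fold's training scores.
    Fully deterministic; the report is invariant (up to per-sample row
    order) under permutation of the input.
    """
    labels = np.asarray(labels, dtype=int)
    n = fm.n_samples
    if n < 3:
        raise EvaluationError("jackknife needs n >= 3")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise EvaluationError("jackknife needs >= 2 samples per class")
    trainer = trainer or _default_trainer
    all_idx = np.arange(n)
    scores = np.empty(n)
    pred = np.empty(n, dtype=int)
    thetas: list[float] = []
    for i in range(n):
        train = np.delete(all_idx, i)
        s, p, th = _resolve_fold(
            fm, labels, train, np.array([i]), trainer, theta
        )
        scores[i], pred[i] = s[0], p[0]
        thetas.append(th)
    theta_used = "per-fold-tuned" if theta == "tune" else float(theta)
    return _pooled_report(
        fm.sample_ids, labels, scores, pred, "jackknife", theta_used, thetas
    )


def kfold(
    fm: FeatureMatrix,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    trainer: Trainer | None = None,
    theta: float | str = 0.0,
) -> EvalReport:
    """Stratified k-fold evaluation pooled over held-out predictions.

    Folds come from a seeded within-class shuffle with round-robin
    assignment, so a fixed seed reproduces the report bit-exactly.
    With k = n this reduces to the jackknife.
    """
    labels = np.asarray(labels, dtype=int)
    trainer = trainer or _default_trainer
    folds = stratified_fold_indices(labels, k, seed)
    n = fm.n_samples
    all_idx = np.arange(n)
    scores = np.empty(n)
    pred = np.empty(n, dtype=int)
    thetas: list[float] = []
    for fold in folds:
        if len(fold) == 0:
            continue
        train = np.setdiff1d(all_idx, fold)
        s, p, th = _resolve_fold(fm, labels, train, fold, trainer, theta)
        scores[fold], pred[fold] = s, p
        thetas.append(th)
    theta_used = "per-fold-tuned" if theta == "tune" else float(theta)
    return _pooled_report(
        fm.sample_ids,
        labels,
        scores,
        pred,
        f"kfold(k={k}, seed={seed})",
        theta_used,
        thetas,
    )


def independent_test(
    results: NaiveBayesResults,
    fm: FeatureMatrix,
    labels: np.ndarray | None = None,
    theta: float | None = None,
) -> EvalReport:
    """Score an independent set with a fitted model.

    Predictions are reported in input order with Antioxidant /
    Nonantioxidant calls. When ``labels`` is omitted the set is assumed
    all-positive (the typical use: experimentally confirmed positives),
    so specificity is undefined and ``n_correct`` counts true positives.
    """
    if fm.n_samples == 0:
        raise EvaluationError("empty test set")
    if labels is None:
        labels = np.ones(fm.n_samples, dtype=int)
    labels = np.asarray(labels, dtype=int)
    pred, scores = results.predict(fm, theta=theta)
    theta_used = results.theta if theta is None else float(theta)
    return _pooled_report(
        fm.sample_ids, labels, scores, pred, "independent", theta_used
    )
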