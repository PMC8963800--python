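"""Classification metrics, ROC/AUC, cross-validation driver and grid search.

Threshold metrics (accuracy, sensitivity, precision, specificity, MCC) are
computed from the confusion matrix with class 1 as positive; a metric whose
denominator is zero is reported as undefined (``None``), never coerced to 0.
The ROC score is the ensemble's positive-class confidence; tied scores are
grouped at a single threshold so the trapezoidal AUC equals the
Mann-Whitney rank statistic with ties counted one half.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ppitex.dataset import InteractionDataset, kfold_split
from ppitex.rotation_forest import RofConfig, fit as rof_fit, predict_proba

_METRIC_NAMES = ("accuracy", "sensitivity", "precision", "specificity", "mcc", "auc")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Metric values in [0,1] (mcc in [-1,1]); ``None`` marks undefined."""

    accuracy: float | None = None
    sensitivity: float | None = None
    precision: float | None = None
    specificity: float | None = None
    mcc: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with class 1 = positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
        return None
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, precision, specificity and MCC from counts."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tn + fp) * float(tp + fn) * float(tn + fn)
    )
    if mcc_den == 0:
        warnings.warn("mcc undefined (zero denominator)", RuntimeWarning)
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        accuracy=(tp + tn) / counts.total,
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        precision=_ratio(tp, tp + fp, "precision"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        mcc=mcc,
    )


def roc_curve_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) at each distinct threshold, plus trapezoidal AUC.

    Tied scores are grouped at one threshold, which makes the trapezoidal
    area equal to the Mann-Whitney U statistic divided by n_pos * n_neg with
    ties counted one half.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores length mismatch")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present in y_true")

    order = np.argsort(-scores, kind="stable")
    ys = y_true[order]
    ss = scores[order]
    # last index of each tied-score group
    ends = np.flatnonzero(np.diff(ss) != 0)
    ends = np.r_[ends, len(ss) - 1]
    tps = np.cumsum(ys == 1)[ends]
    fps = np.cumsum(ys == 0)[ends]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


@dataclass
class CvSummary:
    per_fold: list[MetricsReport]
    mean: dict[str, float | None]
    std: dict[str, float | None]
    k: int
    seed: int


def _summarize(per_fold: list[MetricsReport], k: int, seed: int) -> CvSummary:
    mean: dict[str, float | None] = {}
    std: dict[str, float | None] = {}
    for name in _METRIC_NAMES:
        vals = [getattr(r, name) for r in per_fold if getattr(r, name) is not None]
        if not vals:
            mean[name] = std[name] = None
        else:
            mean[name] = float(np.mean(vals))
            # sample std over folds, matching the mean +/- std presentation
            std[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return CvSummary(per_fold=per_fold, mean=mean, std=std, k=k, seed=seed)


def cross_validate(
    dataset: InteractionDataset,
    config: RofConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CvSummary:
    """k-fold cross-validation of the rotation forest on a pair dataset.

    Each fold in turn is held out, the model is fitted on the remaining k-1
    folds, and threshold metrics plus AUC (scored by the positive-class
    confidence) are computed on the held-out pairs.
    """
    config = config or RofConfig()
    split = kfold_split(len(dataset), k, seed)
    reports: list[MetricsReport] = []
    for fold in split.folds:
        mask = np.ones(len(dataset), dtype=bool)
        mask[fold] = False
        y_train = dataset.Y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                "a training split contains a single class; "
                "use a stratified split or a larger dataset"
            )
        model = rof_fit(dataset.X[mask], y_train, config)
        proba = predict_proba(model, dataset.X[fold])
        pos_col = int(np.flatnonzero(model.classes == 1)[0])
        scores = proba[:, pos_col]
        y_pred = model.classes[np.argmax(proba, axis=1)]
        y_test = dataset.Y[fold]
        report = compute_metrics(confusion_counts(y_test, y_pred))
        if len(np.unique(y_test)) == 2:
            _, report.auc = roc_curve_auc(y_test, scores)
        else:
            warnings.warn("auc undefined (single-class test fold)", RuntimeWarning)
        reports.append(report)
    return _summarize(reports, k=k, seed=seed)


@dataclass
class GridSearchResult:
    best_L: int
    best_K: int
    table: pd.DataFrame


def grid_search(
    dataset: InteractionDataset,
    L_grid: Sequence[int],
    K_grid: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (L, K) search by cross-validated mean accuracy.

    Ties prefer the smaller L, then the smaller K (cheaper ensembles win).
    """
    if not L_grid or not K_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for L in L_grid:
        for K in K_grid:
            summary = cross_validate(
                dataset, RofConfig(L=L, K=K, seed=seed), k=k, seed=seed
            )
            rows.append({"L": L, "K": K, "mean_accuracy": summary.mean["accuracy"]})
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (-r["mean_accuracy"], r["L"], r["K"]))
    return GridSearchResult(best_L=best["L"], best_K=best["K"], table=table)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _fmt(value: float | None, percent: bool) -> str:
    if value is None:
        return "NA"
    return f"{value * 100:.2f}" if percent else f"{value:.4f}"


def cv_summary_rows(summary: CvSummary) -> list[dict]:
    """Rows for the TSV report; percentages to 2 decimals, AUC to 4."""
    rows = []
    for i, rep in enumerate(summary.per_fold, start=1):
        row = {"fold": str(i)}
        for name in _METRIC_NAMES:
            row[name] = _fmt(getattr(rep, name), percent=name != "auc")
        rows.append(row)
    avg = {"fold": "average"}
    for name in _METRIC_NAMES:
        m, s = summary.mean[name], summary.std[name]
        if m is None:
            avg[name] = "NA"
        elif name == "auc":
            avg[name] = f"{m:.4f} +/- {s:.4f}"
        else:
            avg[name] = f"{m * 100:.2f} +/- {s * 100:.2f}"
    rows.append(avg)
    return rows


def write_cv_report(summary: CvSummary, prefix: str | Path, extra: dict | None = None) -> None:
    """Write <prefix>.tsv (formatted table) and <prefix>.json (raw values)."""
    prefix = Path(prefix)
    pd.DataFrame(cv_summary_rows(summary)).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )
    payload = {
        "k": summary.k,
        "seed": summary.seed,
        "per_fold": [r.as_dict() for r in summary.per_fold],
        "mean": summary.mean,
        "std": summary.std,
    }
    if extra:
        payload.update(extra)
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_roc_points(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(path, sep="\t", index=False)
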