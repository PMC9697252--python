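"""Level-wise classification metrics, ROC/AUC, and false positives per scan.

The nodule class is the positive class throughout.  Metrics with a zero
denominator are reported as NaN (undefined), never as 0.  AUC is the area
under the threshold-sweep ROC curve by the trapezoid rule, which equals the
Mann-Whitney statistic P(score+ > score-) + 1/2 P(tie).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (predictions == 1))),
        FP=int(np.sum((labels == 0) & (predictions == 1))),
        TN=int(np.sum((labels == 0) & (predictions == 0))),
        FN=int(np.sum((labels == 1) & (predictions == 0))))


def _ratio(num, den):
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> dict:
    """ACC, sensitivity, specificity and F1 (nodule-positive) from counts.

    ACC is the prevalence-weighted average of sensitivity and specificity, so
    it always lies between them when both are defined.
    """
    if counts.total == 0:
        raise ValueError("no evaluated objects")
    sens = _ratio(counts.TP, counts.TP + counts.FN)
    spec = _ratio(counts.TN, counts.TN + counts.FP)
    precision = _ratio(counts.TP, counts.TP + counts.FP)
    f1 = (_ratio(2 * precision * sens, precision + sens)
          if np.isfinite(precision) and np.isfinite(sens) else float("nan"))
    return {"acc": (counts.TP + counts.TN) / counts.total,
            "sens": sens, "spec": spec, "f1": f1}


def roc_auc(labels, scores):
    """ROC curve points and trapezoid AUC; undefined for single-class labels."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, float)
    if len(np.unique(labels)) < 2:
        return None, float("nan")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thresholds]), float(roc_auc_score(labels, scores))


def fp_per_scan(scan_ids, labels, predictions) -> float:
    """False-positive object calls divided by the number of distinct scans."""
    scan_ids = list(scan_ids)
    if len(scan_ids) == 0:
        raise ValueError("no scans in the evaluated set")
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    n_fp = int(np.sum((labels == 0) & (predictions == 1)))
    return n_fp / len(set(scan_ids))


@dataclass
class EvaluationReport:
    """Per-level metric table with ROC curves and fp/scan."""

    table: pd.DataFrame          # columns level,perspective,acc,auc,f1,sens,spec
    roc_curves: dict             # (level, perspective) -> (fpr, tpr, thr) array
    fp_per_scan: float
    n_scans: int
    n_objects: int

    def to_json(self, path=None):
        payload = {
            "metrics": self.table.to_dict(orient="records"),
            "fp_per_scan": self.fp_per_scan,
            "n_scans": self.n_scans,
            "n_objects": self.n_objects,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def level_report(results, test_vois) -> EvaluationReport:
    """Metrics at every level of a fitted hierarchical fusion model.

    Slice level treats individual slices (with inherited VOI labels) as the
    evaluation unit per perspective; perspective and volume levels treat VOIs
    as units.  ``results`` must expose ``predict_levels``.
    """
    test_vois = list(test_vois)
    if len(test_vois) == 0:
        raise ValueError("empty test set")
    levels = results.predict_levels(test_vois)
    y = levels["true_labels"]
    perspectives = sorted(["V1", "V2", "V3"])
    rows, curves = [], {}

    for i, p in enumerate(perspectives):
        s = levels["slice_scores"][:, i, :]
        y_slices = np.repeat(y, s.shape[1])
        scores = s.reshape(-1)
        counts = confusion_counts(y_slices, (scores >= 0.5).astype(int))
        curve, auc = roc_auc(y_slices, scores)
        rows.append({"level": "slice", "perspective": p, "auc": auc,
                     **metrics(counts)})
        curves[("slice", p)] = curve

    for i, p in enumerate(perspectives):
        scores = levels["perspective_scores"][:, i]
        counts = confusion_counts(y, (scores >= 0.5).astype(int))
        curve, auc = roc_auc(y, scores)
        rows.append({"level": "perspective", "perspective": p, "auc": auc,
                     **metrics(counts)})
        curves[("perspective", p)] = curve

    v_scores = levels["volume_scores"]
    v_pred = levels["labels"]
    counts = confusion_counts(y, v_pred)
    curve, auc = roc_auc(y, v_scores)
    rows.append({"level": "volume", "perspective": "all", "auc": auc,
                 **metrics(counts)})
    curves[("volume", "all")] = curve

    table = pd.DataFrame(rows)[["level", "perspective", "acc", "auc", "f1",
                                "sens", "spec"]]
    scan_ids = levels["scan_ids"]
    return EvaluationReport(
        table=table, roc_curves=curves,
        fp_per_scan=fp_per_scan(scan_ids, y, v_pred),
        n_scans=len(set(scan_ids)), n_objects=len(test_vois))


def plot_roc(report: EvaluationReport, path, level="volume"):
    """Write the ROC curves of one level to ``path`` (matplotlib figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (lvl, p), curve in report.roc_curves.items():
        if lvl != level or curve is None:
            continue
        ax.plot(curve[:, 0], curve[:, 1], label=f"{lvl} {p}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
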