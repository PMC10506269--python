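"""Multi-label ranking metrics: top-k accuracy, ROC/AUC, PR/AP, reports."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "EvalReport",
    "top_k_accuracy",
    "roc_auc",
    "roc_curve_points",
    "average_precision",
    "pr_curve_points",
    "build_report",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given labels (single class, no positives)."""


def top_k_accuracy(scores: np.ndarray, y: np.ndarray, k: int) -> float:
    """Fraction of samples whose k top-scored classes include a true label.

    Ties are broken deterministically toward the lowest class index.  Samples
    with no true label are excluded from the denominator (logged).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    if scores.shape != y.shape:
        raise ValueError(f"scores shape {scores.shape} != labels shape {y.shape}")
    n, c = scores.shape
    if not 1 <= k <= c:
        raise ValueError(f"k must be in [1, {c}], got {k}")
    has_label = y.sum(axis=1) > 0
    n_valid = int(has_label.sum())
    if n_valid < n:
        warnings.warn(
            f"top_k_accuracy: excluding {n - n_valid} samples with no true label",
            stacklevel=2,
        )
    if n_valid == 0:
        raise UndefinedMetricError("no sample has a true label")
    # stable argsort on -scores breaks ties toward the lowest class index
    topk = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    hit = np.take_along_axis(y, topk, axis=1).any(axis=1)
    return float(hit[has_label].sum() / n_valid)


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError(f"scores shape {scores.shape} != labels shape {labels.shape}")
    return scores, labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the mid-rank Mann-Whitney statistic.

    Equals ``P(score_pos > score_neg) + 0.5 * P(tie)``, which is exactly the
    trapezoidal area under the ROC curve but numerically more robust.
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"roc_auc needs both classes, got {n_pos} positives / {n_neg} negatives"
        )
    ranks = rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points over all distinct thresholds, for plotting."""
    scores, labels = _check_binary(scores, labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("roc curve needs both classes")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    tp = np.cumsum(lab == 1)
    fp = np.cumsum(lab == 0)
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    pts = np.column_stack([fp[distinct] / n_neg, tp[distinct] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise AP over the score-sorted list, no interpolation.

    ``AP = sum_k (R_k - R_{k-1}) * P_k`` with ``P_k``/``R_k`` the precision
    and recall after the k-th highest-scored item.  Tied scores are grouped
    so the result does not depend on their ordering.
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("average_precision needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    tp = np.cumsum(lab == 1)
    k = np.arange(1, s.size + 1)
    # evaluate precision/recall only at the last index of each tied group
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    precision = tp[distinct] / k[distinct]
    recall = tp[distinct] / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def pr_curve_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(recall, precision) points over distinct thresholds."""
    scores, labels = _check_binary(scores, labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("pr curve needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    tp = np.cumsum(lab == 1)
    k = np.arange(1, s.size + 1)
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    return np.column_stack([tp[distinct] / n_pos, tp[distinct] / k[distinct]])


@dataclasses.dataclass
class EvalReport:
    """Per-class and aggregate ranking metrics with the underlying curves.

    Classes whose metric is undefined (single-label column) carry NaN and are
    flagged in ``defined``; macro aggregates average only defined classes.
    """

    class_names: list[str]
    per_class_auc: np.ndarray
    per_class_ap: np.ndarray
    defined: np.ndarray  # bool per class
    macro_auc: float
    macro_ap: float
    micro_auc: float
    micro_ap: float
    top_k_accuracy: dict[int, float]
    roc_points: dict[str, np.ndarray]
    pr_points: dict[str, np.ndarray]

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "per_class_auc": [None if not d else float(v)
                              for v, d in zip(self.per_class_auc, self.defined)],
            "per_class_ap": [None if not d else float(v)
                             for v, d in zip(self.per_class_ap, self.defined)],
            "defined": [bool(d) for d in self.defined],
            "macro_auc": self.macro_auc,
            "macro_ap": self.macro_ap,
            "micro_auc": self.micro_auc,
            "micro_ap": self.micro_ap,
            "top_k_accuracy": {str(k): v for k, v in self.top_k_accuracy.items()},
            "roc_points": {c: p.tolist() for c, p in self.roc_points.items()},
            "pr_points": {c: p.tolist() for c, p in self.pr_points.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        defined = np.asarray(d["defined"], dtype=bool)
        auc = np.asarray([np.nan if v is None else v for v in d["per_class_auc"]])
        ap = np.asarray([np.nan if v is None else v for v in d["per_class_ap"]])
        return cls(
            class_names=list(d["class_names"]),
            per_class_auc=auc,
            per_class_ap=ap,
            defined=defined,
            macro_auc=d["macro_auc"],
            macro_ap=d["macro_ap"],
            micro_auc=d["micro_auc"],
            micro_ap=d["micro_ap"],
            top_k_accuracy={int(k): v for k, v in d["top_k_accuracy"].items()},
            roc_points={c: np.asarray(p) for c, p in d["roc_points"].items()},
            pr_points={c: np.asarray(p) for c, p in d["pr_points"].items()},
        )


def build_report(
    scores: np.ndarray,
    y: np.ndarray,
    class_names: list[str] | None = None,
    ks: tuple[int, ...] = (1, 3),
) -> EvalReport:
    """Compute per-class AUC/AP, macro/micro aggregates and top-k accuracy."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    if scores.shape != y.shape:
        raise ValueError(f"scores shape {scores.shape} != labels shape {y.shape}")
    n, c = scores.shape
    if class_names is None:
        class_names = [f"class_{j}" for j in range(c)]
    if len(class_names) != c:
        raise ValueError("class_names length mismatch")

    auc = np.full(c, np.nan)
    ap = np.full(c, np.nan)
    defined = np.zeros(c, dtype=bool)
    roc_pts: dict[str, np.ndarray] = {}
    pr_pts: dict[str, np.ndarray] = {}
    for j in range(c):
        try:
            auc[j] = roc_auc(scores[:, j], y[:, j])
            ap[j] = average_precision(scores[:, j], y[:, j])
            roc_pts[class_names[j]] = roc_curve_points(scores[:, j], y[:, j])
            pr_pts[class_names[j]] = pr_curve_points(scores[:, j], y[:, j])
            defined[j] = True
        except UndefinedMetricError:
            logger.warning("metrics undefined for class %r", class_names[j])

    if not defined.any():
        raise UndefinedMetricError("no class has defined metrics")
    micro_auc = roc_auc(scores.ravel(), y.ravel())
    micro_ap = average_precision(scores.ravel(), y.ravel())
    topk = {k: top_k_accuracy(scores, y, k) for k in ks if k <= c}
    return EvalReport(
        class_names=list(class_names),
        per_class_auc=auc,
        per_class_ap=ap,
        defined=defined,
        macro_auc=float(auc[defined].mean()),
        macro_ap=float(ap[defined].mean()),
        micro_auc=micro_auc,
        micro_ap=micro_ap,
        top_k_accuracy=topk,
        roc_points=roc_pts,
        pr_points=pr_pts,
    )


def write_report_tables(report: EvalReport, out_dir: str | Path) -> None:
    """TSV metric table plus per-class ROC/PR point files for plotting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.tsv", "w") as fh:
        fh.write("class\tauc\tap\tdefined\n")
        for j, name in enumerate(report.class_names):
            a = "NA" if not report.defined[j] else f"{report.per_class_auc[j]:.6f}"
            p = "NA" if not report.defined[j] else f"{report.per_class_ap[j]:.6f}"
            fh.write(f"{name}\t{a}\t{p}\t{int(report.defined[j])}\n")
        fh.write(f"macro\t{report.macro_auc:.6f}\t{report.macro_ap:.6f}\t1\n")
        fh.write(f"micro\t{report.micro_auc:.6f}\t{report.micro_ap:.6f}\t1\n")
    with open(out / "topk.tsv", "w") as fh:
        fh.write("k\taccuracy\n")
        for k, v in sorted(report.top_k_accuracy.items()):
            fh.write(f"{k}\t{v:.6f}\n")
    curves = out / "curves"
    curves.mkdir(exist_ok=True)
    for name, pts in report.roc_points.items():
        np.savetxt(curves / f"roc_{name}.tsv", pts, delimiter="\t",
                   header="fpr\ttpr", comments="")
    for name, pts in report.pr_points.items():
        np.savetxt(curves / f"pr_{name}.tsv", pts, delimiter="\t",
                   header="recall\tprecision", comments="")
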