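"""Agreement metrics and patient-level bootstrap confidence intervals.

Headline metrics for ordinal grading: quadratic-weighted Cohen's kappa
(QWK, chance-corrected agreement with squared-distance disagreement
weights), overall accuracy, macro-F1 (unweighted mean of one-vs-rest class
F1), and mean absolute grade error (MAE).  Confidence intervals come from a
patient-level bootstrap: patients are resampled with replacement and every
resampled patient contributes *all* of its images, respecting the
within-patient correlation of bilateral knees.

QWK and the counting metrics are implemented directly from their
definitions (the test suite cross-checks them against scikit-learn);
ROC/PR curves are delegated to scikit-learn with trapezoidal AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve


def confusion_matrix(y_true, y_pred, n_classes: int = 5) -> np.ndarray:
    """Counts with rows = true grade, columns = predicted grade."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("need equal-length nonempty label vectors")
    if (np.minimum(y_true, y_pred) < 0).any() or (
        np.maximum(y_true, y_pred) >= n_classes
    ).any():
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def qwk(y_true, y_pred, n_classes: int = 5) -> float:
    """Quadratic-weighted Cohen's kappa.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` with weights
    ``w_ij = (i - j)^2 / (n - 1)^2``, O the observed confusion counts and E
    the outer product of the marginals scaled to the sample total.
    """
    obs = confusion_matrix(y_true, y_pred, n_classes).astype(float)
    n = obs.sum()
    idx = np.arange(n_classes)
    w = (idx[:, None] - idx[None, :]) ** 2 / (n_classes - 1) ** 2
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    denom = (w * expected).sum()
    if denom == 0.0:
        # both marginals degenerate on a single class
        if (w * obs).sum() == 0.0:
            return 1.0
        raise ZeroDivisionError("QWK undefined: degenerate marginals with disagreement")
    return float(1.0 - (w * obs).sum() / denom)


def basic_metrics(y_true, y_pred, n_classes: int = 5) -> dict:
    """Accuracy, MAE, macro-F1 and a per-class precision/recall/F1 table.

    Classes absent from the truth are dropped from the macro average with a
    warning; a class present in truth but never predicted scores F1 = 0.
    """
    cm = confusion_matrix(y_true, y_pred, n_classes)
    n = cm.sum()
    accuracy = np.trace(cm) / n
    idx = np.arange(n_classes)
    mae = (cm * np.abs(idx[:, None] - idx[None, :])).sum() / n

    rows = []
    f1s = []
    for c in range(n_classes):
        tp = cm[c, c]
        support = cm[c, :].sum()
        predicted = cm[:, c].sum()
        precision = tp / predicted if predicted else 0.0
        recall = tp / support if support else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        rows.append(
            dict(grade=c, precision=precision, recall=recall, f1=f1,
                 support=int(support))
        )
        if support:
            f1s.append(f1)
        else:
            warnings.warn(f"grade {c} absent from truth; dropped from macro-F1",
                          stacklevel=2)
    return {
        "accuracy": float(accuracy),
        "mae": float(mae),
        "macro_f1": float(np.mean(f1s)) if f1s else 0.0,
        "per_class": pd.DataFrame(rows),
        "confusion": cm,
    }


def _trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray, mode: str = "binary") -> dict:
    """ROC and PR curves with trapezoidal AUCs.

    ``mode="binary"``: ``scores`` is a 1-D probability vector, ``labels``
    binary.  ``mode="ovr"``: ``scores`` is (N, C) class probabilities and
    ``labels`` integer classes; per-class one-vs-rest curves plus the
    macro-average AUC (over classes with both outcomes present) and the
    micro-average from pooled decisions.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if mode == "binary":
        fpr, tpr, _ = roc_curve(labels, scores)
        prec, rec, _ = precision_recall_curve(labels, scores)
        return {
            "roc": (fpr, tpr),
            "pr": (rec, prec),
            "roc_auc": _trapezoid_auc(fpr, tpr),
            "pr_auc": _trapezoid_auc(rec, prec),
        }
    if mode != "ovr":
        raise ValueError("mode must be 'binary' or 'ovr'")
    n_classes = scores.shape[1]
    per_class = {}
    aucs = []
    for c in range(n_classes):
        pos = (labels == c).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            warnings.warn(f"class {c} lacks both outcomes; excluded from macro AUC",
                          stacklevel=2)
            continue
        fpr, tpr, _ = roc_curve(pos, scores[:, c])
        prec, rec, _ = precision_recall_curve(pos, scores[:, c])
        per_class[c] = {
            "roc": (fpr, tpr),
            "pr": (rec, prec),
            "roc_auc": _trapezoid_auc(fpr, tpr),
            "pr_auc": _trapezoid_auc(rec, prec),
        }
        aucs.append(per_class[c]["roc_auc"])
    pooled_labels = np.concatenate(
        [(labels == c).astype(int) for c in range(n_classes)]
    )
    pooled_scores = np.concatenate([scores[:, c] for c in range(n_classes)])
    fpr, tpr, _ = roc_curve(pooled_labels, pooled_scores)
    return {
        "per_class": per_class,
        "macro_auc": float(np.mean(aucs)) if aucs else float("nan"),
        "micro_auc": _trapezoid_auc(fpr, tpr),
        "micro_roc": (fpr, tpr),
    }


def bootstrap_ci(
    predictions: pd.DataFrame,
    metric,
    B: int = 2000,
    seed: int = 42,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Patient-level percentile bootstrap CI for a metric.

    ``predictions`` must carry ``patient_id``, ``true_grade`` and
    ``pred_grade`` columns; ``metric`` is a callable
    ``(y_true, y_pred) -> float``.  Each of the B resamples draws patients
    with replacement, and a drawn patient contributes all of its images
    (drawn twice -> contributes twice).  Deterministic under ``seed``.
    """
    required = {"patient_id", "true_grade", "pred_grade"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions need columns {sorted(required)}")
    groups = {
        pid: (g["true_grade"].to_numpy(), g["pred_grade"].to_numpy())
        for pid, g in predictions.groupby("patient_id")
    }
    pids = sorted(groups)
    if len(pids) == 1:
        warnings.warn("single patient; degenerate CI equals the point value",
                      stacklevel=2)
        t, p = groups[pids[0]]
        v = float(metric(t, p))
        return v, v
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for b in range(B):
        draw = rng.choice(len(pids), size=len(pids), replace=True)
        ts = np.concatenate([groups[pids[i]][0] for i in draw])
        ps = np.concatenate([groups[pids[i]][1] for i in draw])
        stats[b] = metric(ts, ps)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """Headline metrics with patient-level bootstrap CIs."""

    qwk: float
    accuracy: float
    macro_f1: float
    mae: float
    ci: dict[str, tuple[float, float]]
    per_class: pd.DataFrame
    confusion: np.ndarray
    macro_auc: float | None = None
    micro_auc: float | None = None
    kl_ge2_roc_auc: float | None = None
    kl_ge2_pr_auc: float | None = None
    B: int = 2000
    seed: int = 42

    def to_dict(self) -> dict:
        out = {
            "qwk": self.qwk,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "mae": self.mae,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "per_class": self.per_class.to_dict(orient="records"),
            "confusion": self.confusion.tolist(),
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "kl_ge2_roc_auc": self.kl_ge2_roc_auc,
            "kl_ge2_pr_auc": self.kl_ge2_pr_auc,
            "bootstrap": {"B": self.B, "seed": self.seed},
        }
        return out


def evaluate_predictions(
    predictions: pd.DataFrame,
    n_classes: int = 5,
    B: int = 2000,
    seed: int = 42,
    with_curves: bool = True,
) -> MetricReport:
    """Full report from a predictions table.

    Expects columns ``patient_id, true_grade, pred_grade`` and optionally
    ``p0..p4`` (class probabilities) and ``p_ge2`` for the ROC/PR summaries.
    """
    y = predictions["true_grade"].to_numpy(dtype=int)
    p = predictions["pred_grade"].to_numpy(dtype=int)
    base = basic_metrics(y, p, n_classes)
    point_qwk = qwk(y, p, n_classes)
    ci = {
        "qwk": bootstrap_ci(predictions, lambda t, q: qwk(t, q, n_classes), B, seed),
        "accuracy": bootstrap_ci(predictions, lambda t, q: float(np.mean(t == q)), B, seed),
        "macro_f1": bootstrap_ci(
            predictions,
            lambda t, q: basic_metrics(t, q, n_classes)["macro_f1"],
            B,
            seed,
        ),
        "mae": bootstrap_ci(
            predictions, lambda t, q: float(np.mean(np.abs(t - q))), B, seed
        ),
    }
    report = MetricReport(
        qwk=point_qwk,
        accuracy=base["accuracy"],
        macro_f1=base["macro_f1"],
        mae=base["mae"],
        ci=ci,
        per_class=base["per_class"],
        confusion=base["confusion"],
        B=B,
        seed=seed,
    )
    prob_cols = [f"p{c}" for c in range(n_classes)]
    if with_curves and all(c in predictions.columns for c in prob_cols):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ovr = roc_pr_curves(predictions[prob_cols].to_numpy(), y, mode="ovr")
        report.macro_auc = ovr["macro_auc"]
        report.micro_auc = ovr["micro_auc"]
    if with_curves and "p_ge2" in predictions.columns and n_classes == 5:
        pos = (y >= 2).astype(int)
        if 0 < pos.sum() < len(pos):
            binroc = roc_pr_curves(predictions["p_ge2"].to_numpy(), pos, "binary")
            report.kl_ge2_roc_auc = binroc["roc_auc"]
            report.kl_ge2_pr_auc = binroc["pr_auc"]
    return report
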